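# symbiocomp

Host–endosymbiont transcriptome complementation analysis.

Phloem-feeding insects such as the whitefly *Bemisia tabaci* live on a diet
poor in essential amino acids and carry an obligate bacterial endosymbiont
(*Candidatus Portiera aleyrodidarum*, CPA) that synthesizes them. A pooled
RNA-seq library from such an insect contains transcripts of both partners.
`symbiocomp` implements the desk-scale analysis chain that turns such a mixed
transcript pool into a per-pathway picture of **who provides which enzymatic
step** of each amino-acid biosynthesis pathway:

1. **Origin binning** — each transcript is attributed to the symbiont when
   its best local alignment against the symbiont reference exceeds 90%
   identity (over a minimum 50 bp span), otherwise to the host. The aligner
   is optimal Smith–Waterman with affine gaps over both strands; hit
   significance uses the Karlin–Altschul expectation
   `E = K·m·n·exp(−λS)`, with λ solved from
   `Σ pᵢpⱼ exp(λ·sᵢⱼ) = 1`.
2. **Expression quantification** — reads are assigned to their best-aligning
   transcript (≥95% identity over the read; ties split equally) and
   normalized as `RPKM = count·10⁹ / (total_mapped · length_bp)`. qPCR
   validation uses the ΔΔCt statistic `fold = 2^(−ΔΔCt)`. Transcripts with
   RPKM > 50 are flagged as highly expressed.
3. **Complementation inference** — each pathway step (an EC-number set) gets
   a provider in {host, symbiont, both, none} from the expressed, annotated
   transcripts of each partner; pathways are classified host-complete /
   symbiont-complete / chimeric-complete / incomplete, and **hand-off steps**
   (adjacent steps provided by different single partners, implying metabolite
   transport across the host–symbiont boundary) are reported — e.g. the
   terminal branched-chain aminotransferase step (EC 2.6.1.42) that the host
   contributes to the otherwise symbiont-encoded Val/Leu/Ile pathway.
4. **Homolog screening** — putative homologs (e.g. of aphid amino-acid
   transporters) at blast-like thresholds: E ≤ 10⁻⁶, identity and query
   coverage > 60%, top hit only.

A synthetic-community module generates two-organism transcript pools with
known origins, planted EC annotations and read sets with known abundances,
so the entire chain is validated against ground truth. Packaged TSV fixtures
carry the published assembly summary, pathway/expression table and
transporter homolog table, so no downloads are needed.

## Worked example

```python
import symbiocomp as sc

spec = sc.CommunitySpec(n_host=10, n_symbiont=10, seed=7)
reference, pool, truth = sc.generate_community(spec)

calls = sc.classify_origins(pool, reference)
reads = sc.simulate_reads(pool, truth, 2000, error_rate=0.01, seed=8)
records = sc.quantify_expression(reads, pool)
report = sc.build_complementation_report(
    sc.default_pathways(),
    {c.transcript_id: c.origin for c in calls},
    records,
    {t.id: t.ec_annotations for t in pool if t.ec_annotations},
)
for p in report.pathways:
    if p.essential:
        print(f"{p.amino_acid:<26} {p.status:<18} handoffs={list(p.handoffs)}")
```

prints

```
arginine                   symbiont_complete  handoffs=[]
histidine                  symbiont_complete  handoffs=[]
lysine                     symbiont_complete  handoffs=[]
methionine                 symbiont_complete  handoffs=[]
phenylalanine              chimeric_complete  handoffs=[(2, 'symbiont', 'host')]
threonine                  symbiont_complete  handoffs=[]
tryptophan                 symbiont_complete  handoffs=[]
valine_leucine_isoleucine  chimeric_complete  handoffs=[(6, 'symbiont', 'host')]
```

i.e. the essential amino-acid pathways are encoded by the symbiont except
for the terminal aminotransferase steps of phenylalanine and of the
branched-chain amino acids, which the host provides — a symbiont→host
hand-off of the immediate precursor at the last step of each. All 20/20
origin calls match the planted truth at the default 2% (symbiont) vs 30%
(host) divergence from the reference.

The same operations are available from a shell via the `symbiocomp` CLI
(`simulate`, `bin`, `quant`, `summarize`, `homologs`, `complement`).

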