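# vustruct

Missense variants of uncertain significance (VUS) in 3D protein structural
context — a desk-scale, fully offline pipeline for clinical-genomics and
structural-bioinformatics researchers.

Given a case of candidate variants (genomic SNVs in VCF, or protein-level
substitutions in a simple CSV dialect), the pipeline:

1. **Ingests** the case: SNVs are located inside toy transcript CDS models,
   the affected codon is re-translated, and missense changes become
   protein-level variants (`G → P → C282Y`-style records with inheritance).
2. **Reconciles** transcript and curated protein sequences, classifying each
   cross-reference as `PERFECT`, `LEN_MATCH_SEQ_MISMATCH`, `LEN_MISMATCH` or
   `NO_XREF`; only perfectly cross-referenced transcripts proceed, every
   variant is fanned out across the protein's curated "-N" splice isoforms,
   and unprocessable variants stop the run with a machine-readable halt
   report (`--force` proceeds on the retained subset).
3. **Selects structures** per variant from a local catalog of experimental
   structures and computed models, using explicit SIFTS-style residue maps
   and a greedy additive utility

   *u* = *w*<sub>cov</sub>·cov + *w*<sub>div</sub>·div + *w*<sub>qual</sub>·q + *w*<sub>mult</sub>·mult − *w*<sub>red</sub>·overlap

   (coverage of the variant, technique diversity, normalized resolution /
   model confidence, multimer priority, Jaccard redundancy penalty;
   defaults 4/1/1/1/2).
4. **Plans and runs jobs** under an isolated `VUStruct/<case>_<GUID>/`
   hierarchy (`transcript / structure / calculation / {work,status}`), with a
   crash-tolerant append-only status-file protocol and pluggable executors.
   The spatial-clustering analysis runs natively; licensed / ML calculators
   (ΔΔG stability, interface disruption, PTM sites, digenic pairs) ship as
   deterministic stubs with the identical execution contract.
5. **Scores clustering**: for a query residue *q*,
   `score(q) = mean K(d(q, pathogenic sites)) − mean K(d(q, benign sites))`
   with kernel `K(d) = 1/(1+d)` on Cα distances (Å), leave-one-out for the
   query's own residue, and a permutation null that relocates both site sets
   uniformly over the chain's mapped residues
   (`p = (1 + #{null ≥ obs}) / (1 + n_perm)`).
6. **Reports**: a case-wide landing page whose rows show each metric as a
   `[min, max]` range over structures and isoforms (with a machine-readable
   CSV twin), per-transcript pages with a domain-track graphic and
   per-structure result blocks, per-residue score tracks for backbone
   colouring, and a one-line-per-variant flagged case summary spreadsheet.

A synthetic-fixture module generates every input offline — toy
transcriptomes with controlled cross-reference discrepancies, ideal-helix
PDB structures with known coverage/quality/multimericity, spatially planted
pathogenic/benign site sets with ground truth, VCF cases and precomputed
score tables — so the whole pipeline is testable without any download.

## Worked example

```bash
vustruct fixtures --seed 11 --out demo        # synthetic catalog bundle + case
vustruct run --bundle demo --vcf demo/case.vcf --case-id demo1 --out demo_out --seed 5
```

which prints (paths abbreviated):

```
bundle in demo: 5 expected missense variants
case root: demo_out/VUStruct/demo1_<guid>
5/5 variants retained, 10 after isoform expansion, 106 jobs
html: .../report/index.html
csv: .../report/case_report.csv
case_summary: .../report/case_summary.csv
```

Five genomic SNVs were called missense and retained; isoform expansion maps
each onto its protein's canonical and "-2" isoforms (10 protein-level
variants); 106 jobs cover every variant × selected structure × calculation
plus sequence-level and gene-pair jobs. The case summary then reads, e.g.:

```
gene,variant,n_isoforms,destabilizing_ddg,pathogenic_clustering,interface_hit,ptm_hit,digenic_partners,recommendation
G0001,D8Y,2,X,,,X,G0003;G0004;G0005,
```

i.e. for variant D8Y in gene G0001 the (stub) stability change exceeded the
2.0 flag threshold, no significant spatial clustering with pathogenic sites
was found (permutation p > 0.05 on every selected structure), the PTM-site
score crossed its 0.5 threshold, and G0003/G0004/G0005 are candidate
digenic partners. The `recommendation` column is deliberately blank for the
analyst.

Individual stages are also available as `vustruct ingest | xref | pathprox |
scores | report`, and as library functions (`vustruct.ingest`,
`vustruct.xref`, `vustruct.structsel`, `vustruct.pathprox`,
`vustruct.planner`, `vustruct.scores`, `vustruct.report`,
`vustruct.fixtures`).

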