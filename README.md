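# plastorigin

Origin typing of nucleus-encoded plastid-pathway proteins from gene trees.

Dinoflagellates with "non-canonical" plastids (haptophyte- or green-alga-
derived) run plastid-localized pathways with enzymes of mixed evolutionary
provenance. `plastorigin` classifies each query protein from a gene tree with
dual edge supports (ML bootstrap percentage and Bayesian posterior) as:

* **VI** — vertically inherited: nested, with support, among the host
  (peridinin-dinoflagellate-like) reference group;
* **EA** — endosymbiotically acquired: nested among the endosymbiont group;
* **LA** — laterally acquired: nested in a single foreign donor group, or
  called by exclusion when both host and endosymbiont form supported clades
  that exclude the query;
* **UNCERTAIN** — anything without sufficient signal.

It also detects N-terminal extensions (candidate plastid-targeting
presequences) against bacterial reference homologs, ingests external SP/TP
predictions with the conditional SP-then-TP order, flags cytosolic paralogs,
and aggregates calls into a pathway × species × step origin matrix over three
registered pathways (heme C5, chlorophyll *a*, non-mevalonate IPP).

A synthetic gene-family generator (group-structured scenario trees, Poisson
amino-acid evolution) plus an in-house NJ + nonparametric-bootstrap
reconstruction stage make the whole pipeline runnable with no external data
or tools.

## Command line

```bash
# pathway/step/KO-identifier registry
plastorigin registry dump --format tsv

# classify query tips in a newick gene tree
plastorigin classify --tree fam.nwk --taxa taxa.tsv --query Q1,Q2 \
    --config classify.yaml --out calls.tsv

# N-terminal extension vs bacterial references, with SignalP/ChloroP table
plastorigin extension --msa aln.fasta --query Q1 --refs b1,b2,b3 \
    --min-len 10 --preds preds.tsv

# synthetic family with known scenario
plastorigin simulate --scenario EA --n-host 6 --n-endo 6 \
    --donors diatom:4,chlora:4 --n-outgroup 3 --length 500 --seed 42 \
    --out-prefix fam1

# NJ + bootstrap reconstruction (consumed by classify like any treefile)
plastorigin reconstruct --msa fam1.fasta --bootstrap 100 --seed 7 \
    --out fam1.nj.nwk

# full simulate -> reconstruct -> classify -> report run
plastorigin pipeline --config run.yaml --outdir out/
```

### File formats

* **Trees**: newick; internal-node labels are empty, a single number, or
  `MLBP/BPP` (e.g. `98/0.99`). A lone number >1 is read as a bootstrap
  percentage, otherwise as a posterior; override with `--label-as`.
* **Taxon maps**: one 3-column TSV `tip  group  role` (roles:
  `host_vertical`, `endosymbiont`, `donor`, `heterotroph`, `outgroup`, plus
  `query`/`coquery` rows for focal tips), or 2-column tip/group + group/role
  files.
* **Alignments**: FASTA with `-` gaps. **Predictions**: TSV `id  sp  tp`.

### Classification thresholds

Defaults (`mlbp_min=50`, `bpp_min=0.95`, rule `or`, `max_foreign_tips=0`)
are configurable via a YAML file whose keys mirror `ClassificationConfig`;
`max_foreign_tips: 1` tolerates a single intruding tip in otherwise pure
clades, and `long_branch_factor` enables the long-branch exclusion
re-analysis convention.

## Layout

| module | contents |
| --- | --- |
| `plastorigin.registry` | three-pathway step/KOID registry (JSON-backed) |
| `plastorigin.trees` | newick I/O with dual supports, rerooting, splits |
| `plastorigin.taxa` | tip→group→role maps, tree/map validation |
| `plastorigin.classify` | support rule, clade walk, VI/EA/LA/UNCERTAIN cascade |
| `plastorigin.extensions` | N-terminal extension detection, SP/TP ingestion |
| `plastorigin.simulate` | scenario trees + Poisson sequence evolution |
| `plastorigin.reconstruct` | p-distances, Poisson correction, NJ, bootstrap |
| `plastorigin.report` | origin matrix, TSV/text rendering, pipeline driver |
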