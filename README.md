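# cnvkin

Tools for the computational pipeline of a family-cohort SNP-array study:
dual-caller CNV consensus calling, sample and CNV quality-control
filtering, pathogenic CNV/gene annotation, IBD-based relationship and
sex/ancestry checks, and polygenic-score (PGS) cohort statistics — plus a
synthetic-data generator that emulates every input with planted ground
truth, so the whole pipeline is testable without any restricted-access
data.

## Modules

| module | what it does |
| --- | --- |
| `cnvkin.simulate` | synthetic cohorts on a miniature genome: trios/quads with Mendelian-consistent genotypes, group-structured PGS, relationship-typical IBD statistics, fragmented/jittered dual-caller CNV views, reference tracks |
| `cnvkin.consensus` | greedy merging of fragmented per-caller CNV calls (100 kb gap rule, then 25%-of-neighbour rule, to a fixpoint) and reciprocal-overlap consensus between two callers |
| `cnvkin.filters` | sample-level intensity QC (3-SD rule, aneuploidy fraction), common-region mask from base-level call coverage, and the ordered CNV exclusion cascade with a per-CNV audit trail |
| `cnvkin.annotate` | overlap percentages against reference regions, critical-gene / 80%-of-region pathogenic matching, deletion-vs-duplication gene rules, cytoband assignment, large/familial CNV reports |
| `cnvkin.kinship` | relationship classification from PI_HAT/Z0/Z1/Z2, X-inbreeding sex checks with the consanguinity rescue rule, trio Mendelian error rates, 4-SD PC ancestry assignment, nearest-neighbour control matching |
| `cnvkin.pgs` | dosage-by-weight scoring, control-referenced standardization, unpooled Z-tests, the mid-parent transmission-deviation (pTDT) test, spouse correlation, backwards-stepwise residualized prediction with delta-R², Bonferroni flags, analytic power |

Coordinates are 1-based inclusive throughout; BED files (0-based
half-open) are converted on read/write.

## CLI

An umbrella command `cnvkin` plus standalone scripts:

```sh
simulate --config config.yaml --out outdir --seed 1
cnv-consensus --penn caller_a.rawcnv --other caller_b.tsv --out consensus.tsv \
    [--min-overlap 0.5 --max-gap 100000 --gap-fraction 0.25 --trigger 5]
cnv-filter --calls consensus.tsv --resources resources.yaml \
    --out-retained kept.tsv --out-audit audit.tsv
cnv-annotate --calls kept.tsv --pathogenic regions.tsv --genes genes.tsv \
    --cytobands cytobands.bed --out annotated.tsv
kinship classify|mendel|ancestry|match-controls ...
pgs score|power|group-test ...
```

`resources.yaml` maps resource names (centromeres, mhc_region, segdups,
benign_catalog, common_external, exons, gnomad_freqs) to BED/TSV paths;
`simulate` writes a complete, mutually consistent set of these.

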