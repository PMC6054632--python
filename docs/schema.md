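# On-disk formats

All tables are plain text; TSV/CSV files carry a header row.  Readers
preserve gene order, treat T and U as equivalent in sequences, and raise
`bruchase.io.FormatError` with file/line context on malformed input.

## counts.tsv (TSV)
| column | type | notes |
|---|---|---|
| gene_id | string | row key, unique |
| `<library_id>` ... | int ≥ 0 | one column per library |

Library sizes default to column sums; externally mapped totals may be
supplied to `compute_rpkm`.

## samples.csv (CSV)
| column | type | notes |
|---|---|---|
| library_id | string | unique |
| subject_id | string | pairs pulse/chase with replicate |
| group | string | e.g. control, C9ALS, sALS, TDP43_OE |
| assay | enum | `pulse` or `chase` |
| replicate | int ≥ 1 | (subject_id, replicate, assay) unique |

Every chase library must have a pulse partner with the same
(subject_id, replicate).

## gene_models.tsv (TSV)
| column | type | notes |
|---|---|---|
| gene_id | string | row key, unique |
| length_bp | int ≥ 1 | transcript length |
| utr3_len_bp | int | ≤ length_bp |
| intron_count | int ≥ 0 | |
| strand | `+`/`-`/`.` | optional |
| chrom, start, end | optional | 0-based half-open (BED convention) |

## gene_sets.gmt (GMT)
`set_name <TAB> description <TAB> member1 <TAB> member2 ...` — at least
three fields per line; members deduplicated, order kept.

## utr3.fasta (FASTA)
Records keyed by the gene_id token before the first whitespace; U is
normalized to T on read.

## motifs.tsv (TSV)
| column | type | notes |
|---|---|---|
| motif_name | string | unique |
| pattern | IUPAC string | RNA or DNA alphabet |
| rbp | string | optional associated RBP |

## protein.tsv (TSV, long format)
| column | type | notes |
|---|---|---|
| gene_id | string | |
| group | string | |
| replicate | int | optional; omit for pre-averaged tables |
| abundance | float > 0 | arbitrary MS units |
| significant | bool | optional significance flag |

## truth.tsv (TSV, simulate mode)
gene_id, group, alpha (copies/h), k (1/h), expected_stability (the exact
large-depth limit of the stability index, normalization included).

## Stage outputs
`expression.tsv` (gene × library RPKM), `stability.tsv` (gene_id, s_case,
s_control, ratio, class, half_life_*_h), `synthesis.tsv` (gene_id,
base_mean, log2fc, p, q, phi_used, tested, passes),
`synthesis_volcano.tsv` (gene_id, log2fc, neg_log10_q, formatted for
external volcano plotting), `enrichment_*.tsv`
(set_name, k, n, K, N, p, fold_enrichment, q, significant),
`features.tsv` (feature_name, rho, p_perm, n), `motif_enrichment.tsv`
(motif_name, pattern, densities, presence_odds_ratio, fisher_p,
mannwhitney_p, q), `concordance.tsv` (gene_id, stability_class,
protein_change, protein_direction, concordant), `regression.json`,
`pathway_protein_anova.tsv`, `summary.json`, `manifest.json`
(file → sha256), `run.log`, `config.yaml`.
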