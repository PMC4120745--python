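# Bundled reference data

## `table1.tsv`

A curated per-subgroup reference table of ORF1 domain annotations for the 20
Jockey-superfamily subgroups used as the classifier regression fixture
(10 L2, 2 Jockey, 8 CR1 subgroups).

Columns:

| column            | meaning                                                            |
|-------------------|--------------------------------------------------------------------|
| `subgroup`        | lineage + subgroup number, e.g. `L2_3`                              |
| `lineage`         | one of `CR1`, `L2`, `Jockey`                                        |
| `n_seqs`          | number of full-length elements in the subgroup                      |
| `rt_identity_pct` | mean pairwise amino-acid identity of the RT domain (%)              |
| `type_subtype`    | ORF1 type (I–V) + subtype (A–C); blank if not assigned              |
| `domain`          | domain annotated on the ORF1, in N→C order; `none` if no hits       |
| `length_aa`       | minimum observed domain length (aa)                                 |
| `aa_identity_pct` | mean pairwise amino-acid identity of the domain alignment (%)       |
| `top_hit`         | best profile database hit (RCSB / Pfam / Panther identifier)        |
| `probability_pct` | match probability of the top hit (%)                                |
| `n_copies`        | tandem copy number of the domain; blank means unrecorded (read 1)   |

Blank cells are genuinely missing values and are loaded as missing, never as
zero.

### Element counts

The 20 subgroups sum to **448** elements. The underlying curation started from
1,249 downloaded Jockey-superfamily entries; 451 survived completeness
filtering (235 CR1, 87 Jockey, 129 L2), and 3 of those (one CR1, two L2) could
not be placed in any subgroup and were dropped, leaving the 448 tabulated
here. Two of the four `L2_8` elements lack an identifiable ORF1 start but
remain in the subgroup count. `lineorf1.io_formats.load_table1_fixture`
asserts the 448 total.

### Notes on individual rows

- `CR1_2` is typed `V` (unclassified) although a PHD was detected: the
  annotated domains cover less than 10% of the ORF, which overrides the
  architecture grammar. The fixture therefore carries a nominal coverage of
  0.05 for this subgroup (coverages are otherwise not part of the table).
- `CR1_8` has no recorded type; its Tnp22-only architecture classifies as
  `IIA` under the grammar.
- `L2_8` is architecturally identical to `Jockey_1` (2 RRM + 3 CCHC, no PHD,
  grammar type IB) but is recorded as `IC`; reproducing the table requires the
  lineage-context override (see `lineorf1.architecture.CONTEXT_OVERRIDES`).
- The `CC` row of `CR1_3` is a coiled-coil segment inferred from heptad
  periodicity, not a profile hit, so it has no top hit or probability.
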