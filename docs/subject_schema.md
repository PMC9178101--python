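# Subject registry CSV schema

One row per enrolled subject; UTF-8 with a header row. Only the
evidence-bearing fields consumed by the pipeline are listed — real
registries carry thousands of additional longitudinal fields that are not
modelled.

| column | type | meaning |
|--------|------|---------|
| `subject_id` | text, unique | opaque subject token |
| `disease` | text | disease code; each disease belongs to exactly one category |
| `category` | text | one of `amino_acid`, `fatty_acid_oxidation`, `organic_acid`, `other` |
| `gene` | text | gene symbol associated with the disease |
| `transcript` | text | reference transcript accession (versioned; versions are ignored on lookup) |
| `confirmed_dx` | bool | newborn screen plus confirmatory functional test (gates PS3/PP4) |
| `variant_1` | text | first reported variant string, any dialect, may be empty or an invalid token |
| `variant_2` | text | second reported variant string (homozygous subjects repeat the same string) |
| `fh_affected_carrier_variant` | text | variant carried by an affected, genotyped relative (gates PP1) |
| `fh_de_novo_variant` | text | variant reported as de novo (gates PM6) |
| `fh_parents_confirmed` | bool | parentage confirmed for the de novo report (PM6 requires false) |
| `phase_tested` | bool | cis/trans testing performed (provenance only) |
| `in_trans` | bool | phase result when tested (provenance only) |

Boolean columns accept `True`/`False`, `1`/`0`, `yes`/`no`
(case-insensitive); empty cells read as false/empty.
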