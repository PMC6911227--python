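"""Build an ICD-10-CM → phecode map from the fixture terminology.

Constructs the bundled miniature terminology (code lists, GEMS-style
crosswalk, CUI/SNOMED/OHDSI concept tables, ICD-9-CM phecode map), runs
every mapping path, and prints each source code's resolved phecodes with
the path that produced them. Note I10: its GEMS route proposes both 401
"Hypertension" and 401.1 "Essential hypertension", and hierarchy
resolution keeps only the more granular child.
"""

from phemap import Vocabulary, build_fixture_bundle, build_map

bundle = build_fixture_bundle()
pmap = build_map(bundle, Vocabulary.ICD10CM)

print(f"{len(pmap)} mapping records for "
      f"{len(pmap.source_codes())} ICD-10-CM source codes\n")
for record in pmap:
    chain = " -> ".join(
        f"{h.target_vocab.value}:{h.target_code}"
        for h in record.provenance[0]
    )
    print(f"{record.source_code:>8}  ->  {record.phecode:<7} "
          f"[path {record.path_label.value.split('_')[0]}]  via {chain}")

unmapped = sorted(
    set(bundle.code_table(Vocabulary.ICD10CM)["code"]) - pmap.source_codes()
)
print(f"\nunmapped (decoy/administrative) codes: {', '.join(unmapped)}")
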