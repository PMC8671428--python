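"""Parse FAERS-style DRUG/REAC tables into a report-count matrix.

Builds a four-case toy extract in the '$'-separated FAERS ASCII dialect,
joins drug and reaction rows on case id (primary-suspect roles only), and
assembles the drug x side-effect count matrix the models consume.
"""

import io

from sidefactor import build_count_matrix, build_triples, binarize
from sidefactor.faers import parse_drug_table, parse_reac_table

DRUG_TABLE = """\
primaryid$drugname$role_cod
100$aspirin$PS
100$warfarin$SS
101$aspirin$PS
102$warfarin$PS
103$aspirin$PS
103$ibuprofen$C
"""

REAC_TABLE = """\
primaryid$pt
100$Nausea
100$Rash
101$Nausea
102$Bleeding
103$Nausea
"""

drugs = parse_drug_table(io.StringIO(DRUG_TABLE))
reactions = parse_reac_table(io.StringIO(REAC_TABLE))
triples = build_triples(drugs, reactions)

print("(drug, reaction, number of reports) triples:")
for name, term, count in triples:
    print(f"  {name:<10} {term:<10} {count}")

C = build_count_matrix(triples)
A = binarize(C, t=3)
print(f"\ncount matrix: {C.shape[0]} drugs x {C.shape[1]} side effects")
print("counts:\n", C.dense())
print("associations at threshold t=3 (>=3 reports):\n", A.dense())
print("\nASPIRIN/NAUSEA reaches the threshold (3 reports across cases "
      "100, 101, 103); every other pair stays below it, so only that "
      "pair counts as a known association.")
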