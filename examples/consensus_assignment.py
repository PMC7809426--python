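"""The bit-score consensus assignment rules, case by case.

For each query sequence the subjects tied at the maximum bit score decide
the identification rank: one species -> species; several species of one
genus -> genus; several genera of one family -> family; families from
different clades -> excluded.  Queries whose best bit score falls below
the 1st percentile of the run are excluded up front.
"""

import pandas as pd

from meliflora.assign import HIT_COLUMNS, consensus_assign, filter_low_scores
from meliflora.simulate import generate_reference_db

db = generate_reference_db(n_taxa=8, seq_length=500, seed=1)
tax = db.taxonomy


def hits(rows):
    return pd.DataFrame([("q", s, 99.0, 500, b) for s, b in rows],
                        columns=HIT_COLUMNS)


cases = {
    "tie within one species": [("t0000", 500.0), ("t0000", 500.0)],
    "tie across sister species": [("t0000", 500.0), ("t0001", 500.0)],
    "tie across genera, one family": [("t0000", 500.0), ("t0002", 500.0)],
    "tie across families": [("t0000", 500.0), ("t0004", 500.0)],
    "sub-maximal hit ignored": [("t0000", 500.0), ("t0004", 480.0)],
}
for label, rows in cases.items():
    a = consensus_assign(hits(rows), tax)
    print(f"{label:32s} -> status={a.status}, rank={a.rank}, name={a.name}")

# the 1st-percentile bit-score exclusion, on 100 queries scoring 1..100
run = pd.DataFrame(
    [(f"q{i}", "t0000", 99.0, 500, float(i)) for i in range(1, 101)],
    columns=HIT_COLUMNS,
)
kept, excluded = filter_low_scores(run, percentile=0.01)
print(f"\n1st-percentile filter on best scores 1..100: excluded {sorted(excluded)}")
print("(the weakest query of the run is removed before consensus)")
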