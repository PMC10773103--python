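"""The built-in local aligner and the read match criteria.

Aligns an exact read, a mutated read, and a reverse-complemented read
against a subject sequence and shows which survive the screening criteria
(identity > 75%, query coverage > 75%, e-value < 1e-5).
"""

import random

from taxdecon.align import MatchCriteria, local_align, passes_match_criteria, revcomp

rng = random.Random(0)
subject = "".join(rng.choice("ACGT") for _ in range(5000))

read = subject[1000:1100]
mutated = list(read)
for pos in rng.sample(range(len(mutated)), 40):  # 40% mismatches: fails identity
    mutated[pos] = rng.choice("ACGT".replace(mutated[pos], ""))
mutated = "".join(mutated)

criteria = MatchCriteria()
for name, query in (("exact", read), ("mutated", mutated), ("revcomp", revcomp(read))):
    hits = local_align(query, subject, query_id=name)
    if not hits:
        print(f"{name:<8} no alignment above threshold")
        continue
    h = hits[0]
    strand = "+" if h.sstart <= h.send else "-"
    print(
        f"{name:<8} identity={h.percent_identity:6.2f}%  "
        f"subject {min(h.sstart, h.send)}-{max(h.sstart, h.send)} ({strand})  "
        f"bitscore={h.bitscore:6.1f}  e={h.evalue:.2e}  "
        f"match={'yes' if passes_match_criteria(h, criteria) else 'no'}"
    )

print("\nA 'match' must clear all three strict bounds; heavily mutated reads "
      "drop below 75% identity and are not counted, exactly like a read from "
      "an organism with no close relative in the database.")
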