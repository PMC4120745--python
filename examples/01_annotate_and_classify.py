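"""Annotate an ORF1 protein and classify its domain architecture.

Builds a Jockey-style ORF1 (two RRMs upstream of three CCHC zinc knuckles)
from the profile consensus sequences, scans it with the default domain
library, and runs the architecture grammar. The printed hits show 0-based
coordinates, the raw log-odds score, and the calibrated probability that
drives the 85% acceptance rule; the final line is the type/subtype call.
"""
import numpy as np

from lineorf1 import annotate_orf1, architecture_signature, classify_orf1, default_library
from lineorf1.architecture import architecture_from_hits
from lineorf1.io_formats import AA_LETTERS

rng = np.random.default_rng(1)
rand = lambda n: "".join(AA_LETTERS[i] for i in rng.integers(0, 20, n))

library = default_library()
by_name = {p.name: p for p in library}
orf1 = (rand(20)
        + by_name["RRM"].consensus + rand(12)
        + by_name["RRM"].consensus + rand(12)
        + by_name["CCHC"].consensus + rand(12)
        + by_name["CCHC"].consensus + rand(12)
        + by_name["CCHC"].consensus + rand(20))

hits = annotate_orf1(orf1, library, seed=1)
print(f"ORF1 length: {len(orf1)} aa")
for h in hits:
    print(f"  {h.domain:<9} [{h.start:>3}, {h.end:>3})  score={h.score:7.1f}"
          f"  prob={h.probability:5.1f}%  accepted={h.accepted}")

arch = architecture_from_hits(hits, len(orf1))
orf1_type = classify_orf1(arch)
print(f"architecture: {architecture_signature(arch)}  coverage={arch.coverage:.2f}")
print(f"ORF1 type: {orf1_type.label}  "
      "(type I = RRM immediately upstream of CCHC; subtype B = >=2 RRMs with >=3 CCHCs)")
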