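"""Replication fork directionality (RFD) from simulated Okazaki fragments.

RFD = (R - F)/(R + F) per 1 kb bin of strand-split Okazaki-fragment counts:
+1 means purely rightward forks, -1 purely leftward. A single efficient
origin produces a -1 to +1 switch at the origin; forks from two origins
meet at their midpoint, where RFD slopes back down (termination).
"""
import numpy as np

import tripnseq as t
from tripnseq.simulate import SyntheticTruth

genome = t.GenomeModel({"chr1": 1_000_000})
origins = [(250_000, 1.0), (750_000, 1.0)]
truth = SyntheticTruth([], [], {}, {}, {}, {"chr1": origins}, {})

counts = t.simulate_okseq(truth, genome, depth_per_mb=20_000, seed=5)
rfd = t.compute_rfd(counts).data["chr1"]

centers = np.arange(len(rfd)) * 1000 + 500
analytic = t.expected_rfd(origins, centers)
ok = ~np.isnan(rfd)
corr = np.corrcoef(rfd[ok], analytic[ok])[0, 1]

sign = np.sign(rfd[ok])
flips = np.flatnonzero(sign[1:] != sign[:-1])
print(f"origins planted at bins: {[o[0] // 1000 for o in origins]}")
print(f"RFD sign changes at bins: {[int(b) for b in flips + 1]}")
print(f"correlation with analytic fork model: {corr:.3f}")
print(f"RFD at bin 300 (between origin 1 and midpoint): {rfd[300]:+.2f}")
print(f"RFD at bin 600 (termination zone):              {rfd[600]:+.2f}")
print()
print("Sign changes sit at the origins (upward) and at the termination")
print("midpoint (downward); the empirical profile tracks the fork model.")
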