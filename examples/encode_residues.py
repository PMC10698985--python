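"""Build the hybrid feature of one residue under each feature pairing.

Shows the targeted-residue vector and windowed context matrix for the
three encoder pairs (one-hot+entropy, physicochemical+hydropathy,
PSSM+K-PseAA) and how zero padding is masked at sequence ends.
"""

import numpy as np

from ppistack import SyntheticConfig, build_context_matrix, build_targeted_feature, encode_kpseaa
from ppistack.synthetic import attach_mock_pssms, generate_dataset

config = SyntheticConfig(n_sequences=1, seed=1)
(record,) = generate_dataset(config)
attach_mock_pssms([record], config)

i, W = 2, 8  # a residue near the left edge, window half-width 8
for ffmod, name in [(0, "one-hot + entropy density"),
                    (1, "physicochemical + hydropathy"),
                    (2, "PSSM + K-PseAA")]:
    f_tr = build_targeted_feature(record, i, ffmod)
    f_ctx, pad = build_context_matrix(record, i, W, ffmod)
    print(f"ffmod {ffmod} ({name}): f_tr dim {f_tr.shape[0]}, "
          f"context {f_ctx.shape[0]}x{f_ctx.shape[1]}, padded rows {pad.sum()}")

kp = encode_kpseaa(record.sequence, i, K=10, lam=10)
print(f"K-PseAA components sum to {kp.sum():.6f} (composition is normalized)")
print(f"padded context rows are all-zero: {not f_ctx[pad].any()}")
# At position 2 with W=8 the window overhangs the left end by 6 rows,
# which appear as zero rows flagged by the pad mask — the network masks
# them out of attention and pooling.
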