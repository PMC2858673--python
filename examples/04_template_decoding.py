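"""Decode 2D disparity — including the vertical component no encoding
unit is tuned to — by template matching.

Builds a reduced template bank (disparities -4..4, 25 images each; a
couple of CPU-minutes), then decodes noisy single-trial responses to
test stimuli with vertical disparity +2.
"""

import time

import stereopop as sp

enc = sp.EncoderBank()
t0 = time.time()
bank = sp.build_templates(enc, grid=sp.default_grid(4), n_images=25,
                          u=1.0, seed=0)
print(f"template bank: {bank.n_units} units x {bank.n_disparities} "
      f"disparities ({time.time() - t0:.0f} s)")

trials = sp.run_trials(enc, bank, dx=-2, dy=2, n_test=60, u=1.0, seed=1)
s = sp.summarize_trials(trials).iloc[0]
print(f"\n60 noisy trials at true disparity (-2, +2):")
print(trials[["dx_hat", "dy_hat", "max_p"]].head(8).to_string(index=False))
print(f"...\nRMS error: dx {s.rms_dx:.2f} px, dy {s.rms_dy:.2f} px "
      f"(failure rate {s.failure_rate:.2f})")
print("-> the decoder recovers the vertical disparity to sub-pixel "
      "accuracy, although every encoding unit prefers dy = 0")
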