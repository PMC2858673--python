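"""Anticorrelated stereograms drive the encoders but not the decoder.

Contrast-inverting one eye flips every unit's binocular correlation
(C -> -C), so the Pearson match between the response and any stored
template is almost always negative and half-wave rectification silences
the decoding stage — mirroring the absence of depth percepts from
anticorrelated stimuli.
"""

import stereopop as sp

enc = sp.EncoderBank()
bank = sp.build_templates(enc, grid=sp.default_grid(4), n_images=25,
                          u=1.0, seed=0)

corr = sp.run_trials(enc, bank, -2, 2, 60, seed=7, polarity="correlated")
anti = sp.run_trials(enc, bank, -2, 2, 60, seed=7, polarity="anticorrelated")

print(f"mean peak rectified response, correlated:     "
      f"{corr.max_p.mean():.3f}")
print(f"mean peak rectified response, anticorrelated: "
      f"{anti.max_p.mean():.3f}")
print(f"anticorrelated trials flagged degenerate (all-negative Pearson "
      f"map): {anti.degenerate.mean():.0%} vs correlated "
      f"{corr.degenerate.mean():.0%}")
print("-> the anticorrelated response is a noise floor several times "
      "smaller than the correlated peak; its argmax carries no "
      "disparity information")
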