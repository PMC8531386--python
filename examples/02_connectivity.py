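"""Estimate band-resolved wPLI and coherence on a known lagged coupling.

Two channels share an alpha-band (8-10.5 Hz) oscillation injected at a
pi/3 phase lag under sensor noise.  The recording is epoched into 8 s
windows overlapping by 4 s, and both estimators are computed per epoch
from 1 s Hann segments.  wPLI sees only the lagged coupling (it is blind
to zero-lag signals); coherence also picks up amplitude covariance.
"""

import numpy as np

from graphrely import (
    BandDefinition, CouplingSpec, StudyDesign, coherence, default_bands,
    epoch_signal, generate_recording, wpli,
)

alpha1 = BandDefinition("alpha1", 8.0, 10.5)
design = StudyDesign(n_participants=2, duration=60.0, n_channels=2)
spec = CouplingSpec(band=alpha1, edges=((0, 1, 1.0, np.pi / 3),), noise_sd=0.5)
rec = generate_recording(design, spec, strength=0.8, seed=1)
epochs = epoch_signal(rec, 8.0, 4.0, max_epochs=50)
print(f"{epochs.n_epochs} epochs of {epochs.epoch_length:.0f} s "
      f"(overlap {epochs.overlap:.0f} s) from a {design.duration:.0f} s recording")

print("\nband        wPLI    Coh")
for band in default_bands():
    w = wpli(epochs, band).matrices[:, 0, 1].mean()
    c = coherence(epochs, band).matrices[:, 0, 1].mean()
    print(f"{band.name:<8}  {w:.3f}  {c:.3f}")
print("\nOnly alpha-1 carries the coupling: both estimators peak there, "
      "while other bands sit at their finite-sample noise floor.")
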