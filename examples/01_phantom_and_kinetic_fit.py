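"""Generate a DCE-MRI phantom and recover its kinetics voxel ground truth.

Builds a small ellipsoidal-tumor phantom with known extended-Tofts
parameters, converts the noisy SPGR signal back to concentration, fits the
tumor-mean curve, and compares against the generating values.
"""

import numpy as np

import dcecfm
from dcecfm import kinetics as kin

spec = dcecfm.PhantomSpec(ktrans_tumor=0.14, ve_tumor=0.3, vp_tumor=0.04,
                          noise_sd=0.02, seed=7)
ds = dcecfm.generate_phantom(spec)
print(f"phantom: grid {ds.signal.shape[:3]}, {ds.tumor_mask.sum()} tumor voxels, "
      f"{spec.n_frames} frames every {spec.frame_interval_s:.0f} s")

conc = kin.concentration_from_signal(
    ds.signal, ds.t10, spec.tr_s, spec.flip_angle_deg,
    baseline_frames=spec.baseline_frames, times=ds.times)
roi_curve = conc.ct[ds.tumor_mask].mean(axis=0)
fit = kin.fit_etm(roi_curve, ds.times, ds.aif.cp)

print(f"tumor-mean Ktrans: truth {spec.ktrans_tumor:.3f} min^-1, "
      f"fit {fit.ktrans:.3f} min^-1")
print(f"ve: truth {spec.ve_tumor:.2f}, fit {fit.ve:.3f};  "
      f"vp: truth {spec.vp_tumor:.2f}, fit {fit.vp:.3f};  kep {fit.kep:.3f} min^-1")
print("Ktrans is the plasma-to-interstitium transfer constant; at 2% signal "
      "noise the ROI fit lands within a few percent of the generating value.")
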