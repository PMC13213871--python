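"""Compute a hemodynamic force trace on an analytic flow phantom.

Builds a uniformly oscillating velocity field (0.5 m/s amplitude, 1 s cycle,
25 frames, ~100 mL blood pool) at clinical 4D-flow resolution, runs the
Navier-Stokes force pipeline, and compares the peak force with the
closed-form oracle the phantom carries.
"""

import numpy as np

from hemoforce import (
    build_axes,
    compute_hdf,
    make_phantom,
    PhantomSpec,
)

vel, mask, annotation, oracle = make_phantom(PhantomSpec(kind="uniform_oscillation"))
triad = build_axes(annotation, ventricle="LV")
trace, metrics = compute_hdf(vel, mask, triad, es_frame=annotation.es_frame)

peak = float(np.abs(trace.raw).max())
print(f"blood-pool volume      : {oracle.mask_volume_m3 * 1e6:.1f} mL")
print(f"computed peak force    : {peak:.4f} N")
print(f"closed-form peak force : {oracle.peak_force_n:.4f} N")
print(f"relative error         : {abs(peak - oracle.peak_force_n) / oracle.peak_force_n:.2e}")
print(f"apex-base systolic RMS : {metrics.rms['apex_base']['systole']:.4f} N")
print(f"apex-base diastolic RMS: {metrics.rms['apex_base']['diastole']:.4f} N")
# The force is the volume integral of the intraventricular pressure gradient:
# for this phantom it oscillates purely along the apex-base axis, so the
# other two components are zero and the peak matches -rho V dv/dt exactly.
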