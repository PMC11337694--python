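"""From a synthetic ECG to density-map image features, one per split scheme.

Runs the full chain — clean, detect, split (R-R / QRS / S-TP-Q), embed each
cycle with its own tau = T/3, project, bin — and writes one 224 x 224 PNG
per split scheme into ./scratch/.
"""

from pathlib import Path

import psar

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

sig, _ = psar.gen_synthetic_ecg(duration_s=30.0, bpm=65.0, rr_cv=0.1, seed=7)
clean = psar.preprocess_pipeline(sig)
fids = psar.refine_fiducials(clean, psar.detect_r_peaks(clean))

for method in ("RR", "QRS", "STPQ"):
    traj = psar.reconstruct_attractor(clean, fids, method=method, mode="circular")
    pts = psar.project_points(traj)
    dm = psar.make_density_map(pts)
    png = out_dir / f"density_{method.lower()}.png"
    psar.render_image(psar.normalize_density(dm, "log"), png)
    print(f"{method:5s}: {traj.n_cycles} cycles, {len(traj)} points, "
          f"{dm.occupied_bins()} occupied bins -> {png}")
# R-R covers whole beats, QRS isolates the ventricular complex, S-TP-Q the
# low-amplitude T/P region; their occupancy patterns are the image features
# a downstream classifier consumes.
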