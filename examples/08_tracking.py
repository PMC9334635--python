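"""Fluorescence centroid tracking on a rendered synthetic movie.

Renders a noisy two-channel movie from known trajectories (Gaussian PSF,
Poisson shot noise) and recovers the positions by background subtraction
plus intensity-weighted centroiding — the front end of the experimental
analysis chain.
"""

import numpy as np

from cavity_demix import RenderConfig, Trajectory, render_movie, track_movie

rng = np.random.default_rng(3)
steps = 0.03 * rng.standard_normal((60, 2))
true = {
    "green": np.clip(np.array([0.5, 0.2]) + steps.cumsum(axis=0), -1.2, 1.2),
    "red": np.clip(np.array([-0.5, -0.2]) + steps[::-1].cumsum(axis=0), -1.2, 1.2),
}
trajs = {k: Trajectory(v, 0.05, label=k) for k, v in true.items()}

config = RenderConfig(pixel_size=0.05, psf_sigma=0.15,
                      photons_per_frame=5000, background_level=10, seed=1)
stacks, clipped = render_movie(trajs, config)
tracked = track_movie(stacks, config.pixel_size, 0.05, config.origin)

for channel in true:
    err = np.linalg.norm(tracked[channel].positions - true[channel], axis=1)
    print(f"{channel:>5}: RMS tracking error = "
          f"{1e3*np.sqrt((err**2).mean()):.1f} nm "
          f"({np.sqrt((err**2).mean())/config.pixel_size:.2f} px), "
          f"{clipped[channel].sum()} clipped frames")

print("\nWith a 5000-photon budget the centroid noise is far below the "
      "50 nm analysis\nbin, so histogram and dwell statistics are not "
      "tracking-limited.")
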