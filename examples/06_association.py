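"""Cross-channel association against the fitted-simulation null.

Generates two channels: A is a clustered pattern, B sits at 20-nm Gaussian
offsets from A's cluster centers (fully coupled). The association statistic
is the mean nearest-neighbor distance from A to B, compared with the same
statistic after channel A is replaced by fitted Matérn simulations (B held
fixed). Coupled channels show real < simulated; independent channels do
not.
"""

import numpy as np

from replipat import SceneSpec, association_vs_fitted, gen_bivariate, gen_roi
from replipat.synthetic import ChannelBSpec

for coupled in (1.0, 0.0):
    spec = SceneSpec(
        roi_area=2.0, pattern="matern", background_density=0.0, seed=42,
        channel_b=ChannelBSpec(density=30.0, coupled_fraction=coupled,
                               offset_scale=20.0),
    )
    roi = gen_roi(spec)
    a, b, truth = gen_bivariate(roi, spec)
    df = association_vs_fitted(a, b, roi, n_replicates=10,
                               rng=np.random.default_rng(0))
    label = "coupled" if coupled else "independent"
    print(f"{label}: real cross-NND {df.real_mean_nnd_ab[0]:.1f} nm, "
          f"null {df.sim_mean_nnd_ab.mean():.1f} nm "
          f"(real below null in {(df.real_mean_nnd_ab < df.sim_mean_nnd_ab).mean():.0%} "
          f"of replicates)")
print("a real mean well below the null indicates spatial association "
      "between the channels")
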