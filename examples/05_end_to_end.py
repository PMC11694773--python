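"""Full pipeline: phantom -> micro-FE -> spot regions -> counts -> DE.

Generates a bridged-callus phantom, maps its strain field under an
optimised compressive load, embeds a spot grid through a longitudinal
section, simulates NB counts with a "formation" gene set planted in the
high-strain spots, and shows that the strain-stratified statistics recover
the planted signal (set FDR < 0.05, upregulated in high strain).
"""

import numpy as np
import pandas as pd

import mechanomics as mx

spec = mx.PhantomSpec(
    shape=(20, 20, 24), cortex_outer_radius=80.0, cortex_inner_radius=50.0,
    gap_height=70.0, callus_radii=(0.0, 95.0, 100.0), callus_density=460.0,
)
frames, _, _ = mx.make_phantom_timeseries(spec)
mask = mx.threshold_bone(frames[-1])
field = mx.solve_uniaxial(mx.build_fe_model(frames[-1], mask))
rx = mx.optimize_load(
    field, mx.LoadPrescription(target_median_strain=700.0, f_min=0.0, f_max=np.inf),
    mask,
)
field = mx.scale_strains(field, rx.f_applied)
print(f"optimised load {rx.f_applied:.3f} N; median bone strain "
      f"{np.median(field.eff_actual[mask.values]):.0f} ue")

h = field.spacing
rot = np.array([[0.0, 0, -1], [0, 1, 0], [1, 0, 0]])
pose = mx.SectionPose(rot, np.array([(10 + 0.5) * h, 0.0, 0.0]), 5.0)
spots = mx.spot_strain(
    mx.make_spot_grid((5.0, 245.0), (5.0, 205.0), pitch=21.0), field, mask, pose
)
print("spots per region:", spots["region"].value_counts().to_dict())

keep = spots["region"].isin(["high", "reference"])
labels = spots.loc[keep, "region"].to_numpy()
effects = pd.DataFrame({"gene": np.arange(40), "group": "high", "log2fc": 1.5})
cm, _ = mx.simulate_counts(
    labels,
    mx.CountSimSpec(n_genes=1500, mean_log_mu=np.log(20), mean_log_sigma=1.0,
                    dispersion=0.1, effects=effects, seed=77),
)
cm = mx.estimate_size_factors(cm)
scores = mx.gene_set_score(
    cm, labels,
    {"formation_planted": [f"gene{i:05d}" for i in range(40)]},
    groups=("reference", "high"),
)
row = scores.iloc[0]
print(f"planted set: stat {row['stat']:.1f}, FDR {row['fdr']:.2e}, "
      f"direction {row['direction']} (in high vs reference)")
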