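"""Summarize one volume trajectory with AUC1, beta and AUC2.

A tumor that shrinks to 40% of baseline by month 4 and then regrows past
baseline by month 10.  AUC1 is the total area under the ratio curve
(months, since the ratio is dimensionless), beta the average slope per
month, and AUC2 the signed area: the shrinking months count negative, the
regrowth months positive, so AUC2 near zero means the regrowth has undone
the response.
"""

from deltarad import FeatureTrajectory, summarize

traj = FeatureTrajectory(
    patient_id="example",
    feature_name="volume",
    times=[0, 2, 4, 6, 8, 10],
    values=[1.0, 0.55, 0.40, 0.70, 0.95, 1.30],
    normalized=True,
)

tri = summarize(traj)
print(f"AUC1 = {tri.auc1:.3f} ratio-months  (total area under the curve)")
print(f"beta = {tri.beta:+.4f} per month    (overall linear trend)")
print(f"AUC2 = {tri.auc2:+.3f} ratio-months (response minus regrowth balance)")
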