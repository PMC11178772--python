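"""Trajectory analysis: hydrogen bonds, SG–C distances, negative control.

Generates (in memory) one stable trajectory per accepted complex plus a
7 Å negative control, then summarises per-frame hydrogen-bond counts and
SG–C distances. The stable runs plant SG–C quartiles (3.6, 4.4) Å and 7–9
hydrogen bonds; the negative control relaxes from 7 Å onto a (5.5, 6.4) Å
plateau with 2 bonds. Expected outcome: the negative control carries
significantly fewer hydrogen bonds (ANOVA + Holm letters at α = 0.01)
and a clearly higher SG–C distribution.

Writes results/traj_summary.tsv and results/hbond_groups.tsv.
"""

from pathlib import Path

import pandas as pd

from fibryze.posetraj import CatalyticSpec, compare_hbond_groups, traj_summary
from fibryze.synth import gen_trajectory, quartile_profile, relax_profile

ROOT = Path(__file__).resolve().parent.parent / "results"
N_FRAMES = 2000
SEED = 1

COMPLEXES = {  # planted hydrogen-bond counts per complex
    "Aa1": 9, "Aa2": 8, "Aa3": 8, "Bb1": 8, "g1": 7, "g2": 7,
}

summaries, hb_values = [], {}
for i, (name, n_hb) in enumerate(COMPLEXES.items()):
    traj = gen_trajectory(
        N_FRAMES, quartile_profile(N_FRAMES, 3.6, 4.4, seed=SEED + i),
        n_hbonds=n_hb, noise_sigma=0.15, seed=SEED + i,
    )
    sg = traj_summary(traj, "sg_c", spec=CatalyticSpec())
    hb = traj_summary(traj, "hbond", donors_sel={"chain_id": "E"},
                      acceptors_sel={"chain_id": "P"})
    hb_values[name] = hb.values
    summaries.append({"complex": name, "hbond_mean": hb.mean, "sgc_q1": sg.five_number.q1,
                      "sgc_median": sg.five_number.median, "sgc_q3": sg.five_number.q3})

neg = gen_trajectory(
    N_FRAMES, relax_profile(N_FRAMES, 7.0, 5.5, 6.4, seed=SEED + 99),
    n_hbonds=2, noise_sigma=0.15, seed=SEED + 99,
)
sg = traj_summary(neg, "sg_c", spec=CatalyticSpec())
hb = traj_summary(neg, "hbond", donors_sel={"chain_id": "E"}, acceptors_sel={"chain_id": "P"})
hb_values["negative_control"] = hb.values
summaries.append({"complex": "negative_control", "hbond_mean": hb.mean,
                  "sgc_q1": sg.five_number.q1, "sgc_median": sg.five_number.median,
                  "sgc_q3": sg.five_number.q3})

df = pd.DataFrame(summaries).round(3)
df.to_csv(ROOT / "traj_summary.tsv", sep="\t", index=False)
print(df.to_string(index=False))

result, letters = compare_hbond_groups(hb_values, alpha=0.01)
groups = pd.DataFrame(
    [{"complex": g, "hbond_mean": float(hb_values[g].mean()), "letters": letters[g]}
     for g in hb_values]
).round(3)
groups.to_csv(ROOT / "hbond_groups.tsv", sep="\t", index=False)
print(f"\nANOVA over hydrogen-bond counts: F = {result.f_stat:.1f}, p = {result.p_value:.3g}")
print(groups.to_string(index=False))
neg_letters = set(letters["negative_control"])
assert all(neg_letters.isdisjoint(letters[g]) for g in COMPLEXES), \
    "negative control should be distinguishable from every complex"
print("\nnegative control carries significantly fewer hydrogen bonds (α = 0.01)")
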