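"""Integration dynamics for the valence-switch songs.

For each subunit pair, analyses the two 33-subunit songs whose valence
switches after the first third (positive->negative and negative->positive):
mean clamped evidence trajectories (50,000 Monte-Carlo repetitions),
per-step first-passage profiles (density backend, deterministic) and the
thirds decomposition of decision probabilities.

Printed findings: for the negative-first song, the heterospecific pairs
fix most of their rejections within the first third (a veto); for the
positive-first song, the onset-accent pairs delay rejections into the
second third relative to the neutral-block pairs, letting integration
continue to song end.
"""
from pathlib import Path

import pandas as pd

import songdrift as sd
from songdrift.metrics import thirds_decomposition

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = sd.REFERENCE_PARAMS
dcfg = sd.DynamicsConfig(n_reps=50_000, seed=42)

traj_rows, thirds_rows = [], []
for set_id, (pos, neg) in sd.SET_PAIRS.items():
    for pattern in ("switch-at-11", "switch-at-11-reversed"):
        song = sd.build_song(pattern, (pos, neg), set_id=set_id)
        traj = sd.mean_trajectory(song, params, dcfg, backend="mc")
        prof = sd.first_passage_profile(song, params, dcfg, backend="exact")
        thirds = thirds_decomposition(prof)
        traj_rows += [
            {"set_id": set_id, "pattern": pattern, "step": k, "mean_evidence": v}
            for k, v in enumerate(traj)
        ]
        thirds_rows.append(
            {
                "set_id": set_id,
                "pattern": pattern,
                **{f"p_upper_{i+1}": thirds.p_upper_thirds[i] for i in range(3)},
                **{f"p_lower_{i+1}": thirds.p_lower_thirds[i] for i in range(3)},
                "p_end_respond": thirds.p_end_respond,
                "p_end_reject": thirds.p_end_reject,
            }
        )

pd.DataFrame(traj_rows).to_csv(OUT / "mean_trajectories.csv", index=False)
df = pd.DataFrame(thirds_rows)
df.to_csv(OUT / "thirds_decomposition.csv", index=False)

neg_first = df[df.pattern == "switch-at-11-reversed"].set_index("set_id")
pos_first = df[df.pattern == "switch-at-11"].set_index("set_id")
print("negative-first song, first-third rejection mass:")
print(neg_first["p_lower_1"].sort_values(ascending=False).round(3).to_string())
print("\npositive-first song, second-third rejection mass:")
print(pos_first["p_lower_2"].sort_values(ascending=False).round(3).to_string())
het = neg_first.loc[["dorsatus", "mollis"], "p_lower_1"].min()
rest = neg_first.drop(["dorsatus", "mollis"])["p_lower_1"].max()
print(f"\nheterospecific veto: min het {het:.3f} > max other {rest:.3f} -> {het > rest}")
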