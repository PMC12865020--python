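"""Two-stage cluster permutation statistics on group-level TEP maps.

Builds per-subject channel x time TEP maps for 4 sham conditions where
condition 4 carries an extra late frontocentral deflection (140-250 ms),
emulating a PEP-mismatch — the kind of condition difference the analysis
should localize. Runs the repeated-measures cluster ANOVA over 20-300 ms
(stage 1: significant time windows), then the spatial-only cluster test on
window averages with pairwise post-hoc t-tests (stage 2). Also reports an
empirical family-wise-error check under the null at reduced scale.

Writes results/cluster_results.json.
"""

import json

import numpy as np

from tepkit.cluster import ClusterParams, build_neighbors, cluster_ttest, two_stage_test
from tepkit.layout import CHANNELS_64, sensor_positions_2d
from tepkit.simulate import default_tep_components, evaluate_templates, gaussian_topography

N_SUBJECTS = 16
CHANNELS = CHANNELS_64[:32]  # frontocentral/central subset
TIMES = np.arange(0.0, 320.0, 4.0)  # 4 ms grid keeps clustering fast


def group_maps(seed=0):
    rng = np.random.default_rng(seed)
    template = evaluate_templates(
        default_tep_components(CHANNELS, ("M1",))["M1"], TIMES
    )
    late_topo = gaussian_topography("FCz", 0.4, CHANNELS)
    late_bump = np.exp(-((TIMES - 195.0) ** 2) / (2 * 35.0**2))
    effect = 1.5 * np.outer(late_topo, late_bump)  # cond4-only deflection
    conds = []
    for ci in range(4):
        maps = np.empty((N_SUBJECTS, len(CHANNELS), TIMES.size))
        for s in range(N_SUBJECTS):
            gain = 1.0 + 0.2 * rng.standard_normal()
            noise = 0.8 * rng.standard_normal((len(CHANNELS), TIMES.size))
            maps[s] = gain * template + noise
            if ci == 3:
                maps[s] += gain * effect
        conds.append(maps)
    return conds


def main() -> None:
    graph = build_neighbors(
        list(CHANNELS), positions=sensor_positions_2d(CHANNELS),
        rule="knn", k=4,
    )
    params = ClusterParams(test_window_ms=(20.0, 300.0), n_permutations=500)
    conds = group_maps(seed=3)
    res = two_stage_test(conds, graph, params, seed=10, times=TIMES)

    posthoc_summary = []
    for wi, window in enumerate(res.windows):
        pairs = {
            f"cond{i+1}_vs_cond{j+1}": round(min(
                (c.p_value for c in r.clusters), default=1.0), 4)
            for (i, j), r in res.posthoc[wi].items()
        }
        posthoc_summary.append({"window_ms": list(window), "pairwise_p": pairs})

    # reduced-scale null check: 60 repetitions of pure-noise data
    rng = np.random.default_rng(99)
    small = ClusterParams(test_window_ms=(20.0, 300.0), n_permutations=200)
    ring = build_neighbors([f"n{i}" for i in range(6)],
                           positions=np.column_stack(
                               [np.cos(np.arange(6) * np.pi / 3),
                                np.sin(np.arange(6) * np.pi / 3)]),
                           rule="knn", k=2)
    hits = 0
    for rep in range(60):
        a = rng.standard_normal((12, 6, 30))
        b = rng.standard_normal((12, 6, 30))
        null = cluster_ttest(a, b, ring, small, seed=1000 + rep,
                             times=np.linspace(20, 299, 30))
        hits += any(c.p_value < 0.05 for c in null.clusters)

    out = {
        "stage1_windows_ms": [list(w) for w in res.windows],
        "stage1_min_p": round(min((c.p_value for c in res.stage1.clusters),
                                  default=1.0), 4),
        "stage2": posthoc_summary,
        "null_familywise_error_rate": round(hits / 60, 3),
    }
    with open("results/cluster_results.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))
    if res.windows:
        lo, hi = res.windows[0]
        print(f"\nThe cluster ANOVA flags a single late window "
              f"({lo:.0f}-{hi:.0f} ms); post-hoc pairwise tests attribute it "
              f"to condition 4, as constructed. Null FWER at reduced scale: "
              f"{hits / 60:.3f}.")


if __name__ == "__main__":
    main()
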