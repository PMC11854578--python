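"""Adaptive hybrid feature selection on a small synthetic task.

At every forward-selection step, five relevance/redundancy criteria
(mRMR, JMIM, MMIFS, LCFS, plain correlation) each nominate a candidate
feature; nominees are arbitrated by pooled 3-fold CV accuracy of a small
neural net.  Repeated seeded runs give per-feature appearance counts;
features appearing at least once form the prefilter for the clique-based
selector.
"""

import warnings

warnings.filterwarnings("ignore")

from eegsel.ahfs import AHFSConfig, ahfs_run, ahfs_stability
from eegsel.features import build_feature_table, normalize_features
from eegsel.preprocess import PreprocessConfig, run_preprocess
from eegsel.synth import CohortConfig, default_profiles, generate_cohort

cohort = generate_cohort(CohortConfig(
    group_sizes={"CONTROL": 10, "PSF": 10}, duration_s=10.0, fs=256.0, seed=5,
    profiles=default_profiles(),
))
table = normalize_features(build_feature_table(
    [run_preprocess(r, PreprocessConfig()) for r in cohort]
))

trace = ahfs_run(table, AHFSConfig(seed=0, max_steps=5))
print("single run:")
for name, criterion, acc in trace.steps:
    print(f"  +{name:35s} (nominated by {criterion}, pooled CV acc {acc:.2f})")

stability = ahfs_stability(table, n_runs=5, base_seed=0, max_steps=5)
print(f"\n5 runs -> {len(stability.prefilter)} distinct features; most stable:")
for f, c in sorted(stability.counts.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {f}: {c}/5 runs")
# Features at the planted channels (CP5, Fp1) should dominate the stable set.
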