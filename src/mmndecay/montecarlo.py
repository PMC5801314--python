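"""Monte-Carlo evaluations of the analysis chain under known truth.

Because the measurement model is fully synthetic, the package can audit its
own statistical machinery: nested-F calibration under null coupling, type-I
error of the one-tailed MMN-presence test, end-to-end recovery of the
latent ΔMMN-memory coupling through the complete EEG pipeline, and the
stability of the two-component battery solution.  These routines are used
by the test suite and the reproduction script; sample sizes default to the
emulated study (n = 57 analyzed subjects).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cognition
from .scoring import mmn_presence_test
from .simulate import MEMORY_VARS, EF_VARS, SimulationConfig, cohort_frame, simulate_cohort
from .stats import fit_hierarchical
from .study import run_study

__all__ = [
    "ANALYZED_N_PER_GROUP",
    "null_nested_f_pvalues",
    "presence_test_type_one_error",
    "beta_recovery",
    "composite_solution_rates",
]

#: group sizes of the emulated analyzed sample (n = 57)
ANALYZED_N_PER_GROUP = {"SMI": 14, "naMCI": 19, "aMCI": 24}


def _battery_composites(df: pd.DataFrame):
    bat = df[[*MEMORY_VARS, *EF_VARS, "ecb_computation_span"]]
    z, means, sds = cognition.zstandardize(cognition.orient_battery(bat))
    weights = cognition.extract_components(z)
    comps = cognition.build_composites(z, weights)
    mem = [c for c in weights.included if "mvgt_encoding" in weights.included[c]]
    return comps, weights, (mem[0] if mem else None)


def null_nested_f_pvalues(
    n_reps: int = 1000,
    seed: int = 0,
    n_per_group: Optional[dict] = None,
) -> np.ndarray:
    """Nested-F p-values for the decay score under zero coupling.

    Each replicate simulates a cohort whose memory factor is independent of
    the latent ΔMMN (coupling_beta = 0), builds the memory composite via the
    PCA procedure, and tests the latent decay score's added contribution
    over age and education.  Under this null the p-values are uniform.
    """
    ss = np.random.SeedSequence([seed, 101])
    child = ss.generate_state(n_reps)
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        cfg = SimulationConfig(
            n_per_group=n_per_group or ANALYZED_N_PER_GROUP, coupling_beta=0.0
        )
        df = cohort_frame(simulate_cohort(cfg, seed=int(child[i] % 2**31))).set_index(
            "subject_id"
        )
        comps, _, mem_comp = _battery_composites(df)
        data = pd.DataFrame(
            {
                "memory": comps[mem_comp],
                "age_years": df["age_years"],
                "education_years": df["education_years"],
                "delta": df["true_delta_uv"],
            }
        )
        pvals[i] = fit_hierarchical(data, "memory", added="delta").p_change
    return pvals


def presence_test_type_one_error(
    n_reps: int = 2000, n: int = 20, seed: int = 0, alpha: float = 0.05
) -> float:
    """Rejection rate of the one-tailed presence test on zero-mean Gaussian
    amplitude samples (nominal: alpha)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    rejections = 0
    for _ in range(n_reps):
        rejections += mmn_presence_test(rng.standard_normal(n), alpha=alpha)["p"] < alpha
    return rejections / n_reps


def beta_recovery(
    n_reps: int = 200,
    seed: int = 0,
    n_per_group: Optional[dict] = None,
) -> pd.DataFrame:
    """End-to-end coupling recovery through the full EEG pipeline.

    Each replicate simulates a complete cohort (epochs at the study's trial
    counts and the default noise level), runs filtering, rejection,
    averaging, two-stage scoring, outlier exclusion, PCA composites and the
    hierarchical regression, and records the standardized β of the scored
    ΔMMN, its nested-F p, and the paired paradigm-contrast p.

    Only the duration deviant is simulated for the short-ISI paradigm (the
    one ΔMMN is built from); the long-ISI paradigm includes the frequency
    deviant so the outlier rule operates as in the full analysis.
    """
    ss = np.random.SeedSequence([seed, 303])
    child = ss.generate_state(n_reps)
    rows = []
    for i in range(n_reps):
        s = int(child[i] % 2**31)
        cfg = SimulationConfig(n_per_group=n_per_group or ANALYZED_N_PER_GROUP, seed=s)
        res = run_study(cfg, seed=s, opt1_families=("duration",))
        reg = res.regressions["memory~delta_mmn"]
        rows.append(
            {
                "beta": reg.std_beta_full["delta_mmn_uv"],
                "p_change": reg.p_change,
                "delta_r2": reg.delta_r2,
                "contrast_p": res.contrast["p"],
                "contrast_mean_uv": res.contrast["mean_diff_uv"],
                "n_analyzed": len(res.table),
                "n_excluded": len(res.excluded),
            }
        )
    return pd.DataFrame(rows)


def composite_solution_rates(
    n_reps: int = 100, n_total: int = 200, seed: int = 0
) -> dict:
    """Fraction of replicates with exactly two Kaiser components and every
    battery block loading on its own component at |loading| >= 0.50."""
    ss = np.random.SeedSequence([seed, 404])
    child = ss.generate_state(n_reps)
    per = n_total // 3
    two, assigned = 0, 0
    ecb_loadings = []
    for i in range(n_reps):
        cfg = SimulationConfig(
            n_per_group={"SMI": per, "naMCI": per, "aMCI": n_total - 2 * per}
        )
        df = cohort_frame(
            simulate_cohort(cfg, seed=int(child[i] % 2**31))
        ).set_index("subject_id")
        _, weights, mem_comp = _battery_composites(df)
        if weights.n_components == 2:
            two += 1
            other = [c for c in weights.loadings.columns if c != mem_comp][0]
            ok = all(v in weights.included.get(mem_comp, []) for v in MEMORY_VARS) and all(
                v in weights.included.get(other, []) for v in EF_VARS
            )
            assigned += ok
            ecb_loadings.append(float(weights.loadings.loc["ecb_computation_span", other]))
    return {
        "two_component_rate": two / n_reps,
        "block_assignment_rate": assigned / n_reps,
        "mean_ecb_loading": float(np.mean(ecb_loadings)) if ecb_loadings else np.nan,
    }
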