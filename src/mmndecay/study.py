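"""End-to-end driver: simulated cohort -> epochs -> scores -> composites ->
hierarchical regressions, mirroring the full analysis chain.

:func:`run_study` is the one-call entry point; it returns a
:class:`StudyResult` carrying the per-subject score table, ΔMMN values,
outlier exclusions, composite scores, the fitted regression results and the
paired paradigm contrast, with a ``summary()`` for human inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import cognition, erp, scoring
from .paradigms import DEVIANT_FAMILIES
from .simulate import (
    GROUPS,
    SimulationConfig,
    SubjectRecord,
    simulate_cohort,
    simulate_epochs,
)
from .stats import HierarchicalRegression, HierarchicalRegressionResults

__all__ = ["StudyResult", "run_study", "score_cohort"]


@dataclass
class StudyResult:
    config: SimulationConfig
    cohort: list[SubjectRecord]
    scores: pd.DataFrame            # subject x (paradigm, family) amplitudes/latencies
    excluded: list[str]
    table: pd.DataFrame             # merged per-subject analysis table
    weights: cognition.CompositeWeights
    regressions: dict[str, HierarchicalRegressionResults]
    contrast: dict
    presence: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"Simulated cohort: n = {len(self.cohort)} "
            f"({', '.join(f'{g}: {sum(r.group == g for r in self.cohort)}' for g in GROUPS)})",
            f"Excluded by positive-outlier rule: {len(self.excluded)} "
            f"({', '.join(self.excluded) if self.excluded else 'none'})",
            f"Analyzed: n = {len(self.table)}",
            "",
            "Mean scored amplitudes (uV):",
        ]
        for col in self.scores.columns:
            if col.endswith("_uv"):
                lines.append(f"  {col:<24}{self.table[col].mean():>8.2f}")
        c = self.contrast
        lines += [
            "",
            f"Paradigm contrast (long-ISI minus short-ISI duration MMN): "
            f"mean = {c['mean_diff_uv']:.2f} uV, t({c['df']}) = {c['t']:.2f}, p = {c['p']:.2g}",
            "",
        ]
        for name, res in self.regressions.items():
            lines += [f"--- {name} ---", res.summary(), ""]
        return "\n".join(lines)


def score_cohort(
    cohort: Sequence[SubjectRecord],
    config: SimulationConfig,
    seed: int,
    opt1_families: Sequence[str] = DEVIANT_FAMILIES,
    memtra_families: Sequence[str] = ("duration", "frequency"),
    p2p_limit_uv: float = 100.0,
) -> pd.DataFrame:
    """Simulate epochs for every subject, run the ERP chain, anchor scoring
    windows on per-group grand averages, and return the long score table."""
    waves: dict[tuple[str, str], dict[str, erp.ErpWave]] = {}
    for rec in cohort:
        for paradigm, fams in (("opt1", opt1_families), ("memtra", memtra_families)):
            epochsets = simulate_epochs(
                rec, paradigm, config, seed=seed, conditions=("standard", *fams)
            )
            subj_waves, _ = erp.subject_difference_waves(
                epochsets, p2p_limit_uv=p2p_limit_uv
            )
            waves[(rec.subject_id, paradigm)] = subj_waves

    group_of = {r.subject_id: r.group for r in cohort}
    rows = []
    for paradigm, fams in (("opt1", opt1_families), ("memtra", memtra_families)):
        for fam in fams:
            for group in GROUPS:
                members = [
                    r.subject_id
                    for r in cohort
                    if r.group == group and (r.subject_id, paradigm) in waves
                ]
                if not members:
                    continue
                grand = scoring.grand_average(
                    [waves[(s, paradigm)][fam] for s in members]
                )
                peak = scoring.find_group_peak(grand, fam)
                for s in members:
                    sc = scoring.score_subject(waves[(s, paradigm)][fam], peak, fam)
                    rows.append(
                        {
                            "subject_id": s,
                            "group": group_of[s],
                            "paradigm": paradigm,
                            "family": fam,
                            "amplitude_uv": sc.amplitude_uv,
                            "latency_ms": sc.latency_ms,
                            "group_peak_ms": peak,
                        }
                    )
    return pd.DataFrame(rows)


def run_study(
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    opt1_families: Sequence[str] = DEVIANT_FAMILIES,
    memtra_families: Sequence[str] = ("duration", "frequency"),
    p2p_limit_uv: float = 100.0,
) -> StudyResult:
    """Run the whole chain on one simulated cohort."""
    config = config or SimulationConfig()
    seed = config.seed if seed is None else seed
    cohort = simulate_cohort(config, seed=seed)
    long_scores = score_cohort(
        cohort, config, seed, opt1_families, memtra_families, p2p_limit_uv
    )

    wide = long_scores.pivot_table(
        index="subject_id", columns=["paradigm", "family"], values="amplitude_uv"
    )
    wide.columns = [f"{p}_{f}_uv" for p, f in wide.columns]

    # positive-outlier rule on the two long-ISI families
    excluded: list[str] = []
    if {"memtra_duration_uv", "memtra_frequency_uv"} <= set(wide.columns):
        excluded = scoring.flag_positive_outliers(
            wide["memtra_duration_uv"].dropna().to_dict(),
            wide["memtra_frequency_uv"].dropna().to_dict(),
        )
    kept = wide.drop(index=excluded)

    demo = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in cohort],
            "group": [r.group for r in cohort],
            "age_years": [r.age_years for r in cohort],
            "education_years": [r.education_years for r in cohort],
            "true_delta_uv": [r.latent["true_delta_uv"] for r in cohort],
        }
    ).set_index("subject_id")
    battery = pd.DataFrame(
        {v: [r.battery[v] for r in cohort] for v in cohort[0].battery},
        index=demo.index,
    )
    keep_idx = [s for s in demo.index if s not in excluded]
    demo, battery = demo.loc[keep_idx], battery.loc[keep_idx]

    oriented = cognition.orient_battery(battery)
    z, means, sds = cognition.zstandardize(oriented)
    weights = cognition.extract_components(z)
    weights.means, weights.sds = means, sds
    comps = cognition.build_composites(z, weights)
    comps.columns = _label_components(weights)

    table = demo.join(kept).join(comps)
    if {"opt1_duration_uv", "memtra_duration_uv"} <= set(table.columns):
        table["delta_mmn_uv"] = table["opt1_duration_uv"] - table["memtra_duration_uv"]

    regressions: dict[str, HierarchicalRegressionResults] = {}
    for outcome in ("memory", "attention_ef"):
        if outcome not in table.columns:
            continue
        for added, tag in (
            ("delta_mmn_uv", "delta_mmn"),
            ("memtra_duration_uv", "memtra_mmn"),
        ):
            if added in table.columns:
                regressions[f"{outcome}~{tag}"] = HierarchicalRegression(
                    table, outcome, added=(added,)
                ).fit()

    paired = table.dropna(subset=["opt1_duration_uv", "memtra_duration_uv"])
    contrast = scoring.paradigm_contrast(
        paired["opt1_duration_uv"], paired["memtra_duration_uv"]
    )

    presence_rows = []
    for (paradigm, fam), sub in long_scores.groupby(["paradigm", "family"]):
        sub = sub[~sub["subject_id"].isin(excluded)]
        for group, g in sub.groupby("group"):
            if len(g) >= 3:
                rep = scoring.mmn_presence_test(g["amplitude_uv"])
                presence_rows.append(
                    {"paradigm": paradigm, "family": fam, "group": group, **rep}
                )
    presence = pd.DataFrame(presence_rows)

    return StudyResult(
        config=config,
        cohort=cohort,
        scores=wide,
        excluded=excluded,
        table=table,
        weights=weights,
        regressions=regressions,
        contrast=contrast,
        presence=presence,
    )


def _label_components(weights: cognition.CompositeWeights) -> list[str]:
    """Name components by their included variables: the one holding the
    verbal-recall block is 'memory', the other 'attention_ef'."""
    memory_markers = {"mvgt_encoding", "mvgt_recall", "adas_free_recall"}
    labels = []
    for comp in weights.loadings.columns:
        incl = set(weights.included.get(comp, []))
        overlap = len(incl & memory_markers)
        labels.append(("memory", overlap, comp))
    labels.sort(key=lambda t: -t[1])
    out = {}
    if labels:
        out[labels[0][2]] = "memory"
    for _, _, comp in labels[1:]:
        out[comp] = "attention_ef" if len(out) == 1 else f"component_{len(out) + 1}"
    return [out[c] for c in weights.loadings.columns]
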