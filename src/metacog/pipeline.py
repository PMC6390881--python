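"""End-to-end orchestration of the training-study analysis.

Takes a trial-level cohort log (simulated by :mod:`metacog.observers`
or read from CSV) through the full analysis chain: response-time
filtering and participant exclusions, per-session summaries (d', mean
confidence, mean QSR, meta-d', log efficiency, mean difficulty), group
contrast tables, latent change score models of pre/post calibration,
the confidence-shift mediation model, and the artificial
confidence-bias-shift simulation that checks how a pure bias change
moves calibration and efficiency in opposite directions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, metad
from .lcs import fit_bivariate_lcs
from .mediation import MediationData, fit_mediation
from .observers import CohortConfig, simulate_cohort

__all__ = [
    "ExclusionReport",
    "RT_MIN_MS",
    "RT_MAX_MS",
    "filter_rt",
    "apply_exclusions",
    "summarize_sessions",
    "group_contrast_tables",
    "bias_shift_simulation",
    "run_study",
]

# retention is boundary-inclusive: a trial is dropped iff rt < 200 or rt > 2000
RT_MIN_MS = 200.0
RT_MAX_MS = 2000.0

PERFORMANCE_BAND = (0.55, 0.95)
DIFFICULTY_SD_CUTOFF = 2.5
CONF_INVARIANCE_PROP = 0.95
CONF_INVARIANCE_SESSIONS = 3


@dataclass(frozen=True)
class ExclusionReport:
    """Participant-level exclusion flags and RT-filter counts."""

    participant_id: str
    rule: str  # performance-band | difficulty-outlier | confidence-invariance | none
    rt_dropped: int
    rt_dropped_prop: float


def filter_rt(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Drop trials with rt > 2000 ms or rt < 200 ms (strict inequalities)."""
    bad = (cohort["rt_ms"] < RT_MIN_MS) | (cohort["rt_ms"] > RT_MAX_MS)
    dropped = bad.groupby(cohort["participant"]).sum()
    return cohort.loc[~bad].copy(), dropped


def _performance_band_flags(df: pd.DataFrame) -> set[str]:
    acc = df.groupby(["participant", "session", "domain", "stimulus_type"])["accuracy"].mean()
    lo, hi = PERFORMANCE_BAND
    bad = acc[(acc < lo) | (acc > hi)]
    return set(bad.index.get_level_values("participant"))


def _difficulty_flags(df: pd.DataFrame) -> set[str]:
    per = df[df["domain"] == "perception"].copy()
    if per.empty:
        return set()
    per["difficulty"] = calibration.brightness_to_difficulty(per["stimulus_level"].to_numpy())
    mean_diff = per.groupby("participant")["difficulty"].mean()
    group_of = per.groupby("participant")["group"].first()
    flags: set[str] = set()
    for g, vals in mean_diff.groupby(group_of):
        cut = vals.mean() - DIFFICULTY_SD_CUTOFF * vals.std(ddof=1)
        flags |= set(vals.index[vals < cut])
    return flags


def _confidence_invariance_flags(df: pd.DataFrame) -> set[str]:
    def max_prop(s: pd.Series) -> float:
        return s.value_counts(normalize=True).iloc[0]

    prop = df.groupby(["participant", "session"])["confidence"].agg(max_prop)
    invariant = (prop >= CONF_INVARIANCE_PROP).groupby("participant").sum()
    return set(invariant.index[invariant >= CONF_INVARIANCE_SESSIONS])


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, list[ExclusionReport]]:
    """RT-filter the trial log and flag participants by the study rules.

    Participant rules, applied in order (a participant is reported under
    the first rule they trigger): accuracy outside 55–95% correct in any
    condition/session; mean difficulty more than 2.5 SD below the group
    mean; the same confidence level on >= 95% of trials in three or more
    sessions.  All flagged participants are removed from the returned
    cohort.  Deterministic.
    """
    filtered, dropped = filter_rt(cohort)
    n_trials = cohort.groupby("participant").size()
    flags = [
        ("performance-band", _performance_band_flags(filtered)),
        ("difficulty-outlier", _difficulty_flags(filtered)),
        ("confidence-invariance", _confidence_invariance_flags(filtered)),
    ]
    reports: list[ExclusionReport] = []
    excluded: set[str] = set()
    for pid in sorted(n_trials.index):
        rule = "none"
        for name, members in flags:
            if pid in members:
                rule = name
                break
        if rule != "none":
            excluded.add(pid)
        nd = int(dropped.get(pid, 0))
        reports.append(
            ExclusionReport(
                participant_id=pid,
                rule=rule,
                rt_dropped=nd,
                rt_dropped_prop=nd / int(n_trials[pid]),
            )
        )
    return filtered[~filtered["participant"].isin(excluded)].copy(), reports


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

MIN_CELL_TRIALS = 20


def summarize_sessions(cohort: pd.DataFrame, fit_metad: bool = True) -> pd.DataFrame:
    """Per participant-session-condition metric table.

    One row per (participant, session, domain, stimulus_type) with d',
    mean confidence, mean QSR, meta-d', log(meta-d'/d') and, for
    perception, the mean difficulty level.  Cells with fewer than 20
    trials are flagged (``low_n``) rather than dropped.
    """
    rows = []
    keys = ["participant", "group", "session", "phase", "domain", "stimulus_type"]
    for key, cell in cohort.groupby(keys, sort=True):
        qsr = float(
            np.mean(
                calibration.qsr_trial(cell["accuracy"].to_numpy(), cell["confidence"].to_numpy())
            )
        )
        rec = dict(zip(keys, key))
        rec.update(
            n_trials=len(cell),
            low_n=len(cell) < MIN_CELL_TRIALS,
            accuracy=float(cell["accuracy"].mean()),
            mean_confidence=metad.mean_confidence(cell),
            mean_qsr=qsr,
        )
        if key[keys.index("domain")] == "perception":
            rec["mean_difficulty"] = float(
                np.mean(calibration.brightness_to_difficulty(cell["stimulus_level"].to_numpy()))
            )
        else:
            rec["mean_difficulty"] = np.nan
        if fit_metad:
            fit = metad.fit_meta_d(metad.counts_from_trials(cell))
            rec.update(
                d_prime=fit.d_prime,
                meta_d_prime=fit.meta_d_prime,
                ratio=fit.ratio,
                log_ratio=fit.log_ratio,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def group_contrast_tables(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pre/post cell means (+/- SEM) by group, domain and stimulus type.

    Long-format table of the quantities the pre/post group ANOVAs
    consume; rows are (phase, group, domain, stimulus_type, measure).
    """
    pp = summaries[summaries["phase"].isin(["pre", "post"])]
    measures = [
        m for m in ("mean_qsr", "mean_confidence", "d_prime", "log_ratio", "mean_difficulty")
        if m in pp.columns
    ]
    out = []
    for (phase, group, domain, stim), cell in pp.groupby(
        ["phase", "group", "domain", "stimulus_type"]
    ):
        for m in measures:
            v = cell[m].dropna()
            if v.empty:
                continue
            sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
            out.append(
                dict(
                    phase=phase, group=group, domain=domain, stimulus_type=stim,
                    measure=m, mean=float(v.mean()), sem=sem, n=len(v),
                )
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# artificial confidence-bias-shift simulation
# ---------------------------------------------------------------------------

def bias_shift_simulation(
    pre_trials: pd.DataFrame, shift: int
) -> tuple[float, float, pd.DataFrame]:
    """Effect of an artificial uniform confidence shift on calibration.

    Adds ``shift`` (0–3) to every confidence rating of a pretraining
    trial log, clipping at the top of the scale, and recomputes the mean
    QSR and the fitted log(meta-d'/d') per participant.  Around the
    ~75%-correct titration point an upward shift raises the calibration
    score while compressing the confidence scale from above, which
    *lowers* fitted metacognitive efficiency — a pure bias change moves
    the two measures in opposite directions.

    Returns the mean change in QSR, the mean change in log ratio, and
    the per-participant table.
    """
    if shift not in (0, 1, 2, 3):
        raise ValueError("shift must be an integer in 0..3")
    rows = []
    for pid, cell in pre_trials.groupby("participant"):
        base_qsr = float(
            np.mean(calibration.qsr_trial(cell["accuracy"].to_numpy(), cell["confidence"].to_numpy()))
        )
        base_fit = metad.fit_meta_d(metad.counts_from_trials(cell))
        shifted = cell.copy()
        shifted["confidence"] = np.minimum(shifted["confidence"] + shift, 4)
        new_qsr = float(
            np.mean(
                calibration.qsr_trial(shifted["accuracy"].to_numpy(), shifted["confidence"].to_numpy())
            )
        )
        new_fit = metad.fit_meta_d(metad.counts_from_trials(shifted))
        rows.append(
            dict(
                participant=pid,
                d_qsr=new_qsr - base_qsr,
                d_log_ratio=new_fit.log_ratio - base_fit.log_ratio,
            )
        )
    table = pd.DataFrame(rows)
    return float(table["d_qsr"].mean()), float(table["d_log_ratio"].mean()), table


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def _lcs_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Wide pre/post QSR table (trained stimulus type only) for LCS fitting."""
    pp = summaries[summaries["phase"].isin(["pre", "post"])]
    rows = []
    for pid, group in pp.groupby("participant")["group"].first().items():
        sub = pp[pp["participant"] == pid]
        trained = sub["trained_stimulus"].iloc[0] if "trained_stimulus" in sub else None
        if trained is not None:
            sub = sub[sub["stimulus_type"] == trained]
        rec = {"participant": pid, "group": group}
        for dom, col in (("perception", "P"), ("memory", "M")):
            for ph in ("pre", "post"):
                v = sub[(sub["domain"] == dom) & (sub["phase"] == ph)]["mean_qsr"]
                rec[f"{col}_{ph}"] = float(v.iloc[0]) if len(v) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).dropna()


def _mediation_table(
    summaries: pd.DataFrame, early_session: int = 2, mid_session: int = 5
) -> pd.DataFrame:
    """Per-participant X, M, Y for the confidence-shift mediation model.

    M is the early confidence shift (session ``early_session`` minus
    pretraining mean confidence); Y the late efficiency change
    (posttraining minus session ``mid_session`` log ratio).  Perception
    trials only; at pre/post, where both stimulus types were run, the
    per-stimulus cell metrics are averaged (training sessions contain
    only the trained stimulus type).  Participants with an undefined
    log ratio (non-positive meta-d') in any required cell drop out.
    """
    per = summaries[summaries["domain"] == "perception"]
    rows = []
    for pid, cell in per.groupby("participant"):
        by_session = cell.groupby("session")[["mean_confidence", "log_ratio"]].mean()
        need = {1, early_session, mid_session, 10}
        if not need.issubset(set(by_session.index)):
            continue
        rows.append(
            dict(
                participant=pid,
                X=float(cell["group"].iloc[0] == "experimental"),
                M=float(
                    by_session.loc[early_session, "mean_confidence"]
                    - by_session.loc[1, "mean_confidence"]
                ),
                Y=float(
                    by_session.loc[10, "log_ratio"] - by_session.loc[mid_session, "log_ratio"]
                ),
            )
        )
    return pd.DataFrame(rows).dropna()


def run_study(
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_boot: int = 2000,
) -> dict:
    """Simulate and analyse one full study; optionally write all artifacts.

    Pipeline: simulate cohort (staircase titration and feedback
    structure included) -> RT filter and exclusions -> session
    summaries -> group contrast tables -> bivariate LCS on pre/post QSR
    -> confidence-shift mediation -> bias-shift simulation.  Fully
    seeded; a fixed seed reproduces every output byte for byte.
    """
    cfg = config or CohortConfig()
    cohort = simulate_cohort(cfg, seed=seed)
    filtered, reports = apply_exclusions(cohort)
    # carry the trained stimulus label through the summaries
    summaries = summarize_sessions(filtered)
    trained = cohort.groupby("participant")["trained_stimulus"].first()
    summaries["trained_stimulus"] = summaries["participant"].map(trained)

    contrasts = group_contrast_tables(summaries)
    lcs_data = _lcs_table(summaries)
    lcs_fit = fit_bivariate_lcs(lcs_data)
    med_data = _mediation_table(summaries)
    med_fit = fit_mediation(MediationData.from_frame(med_data), n_boot=n_boot, seed=seed + 1)
    pre = filtered[(filtered["phase"] == "pre") & (filtered["domain"] == "perception")]
    dqsr, dlog, shift_table = bias_shift_simulation(pre, shift=1)

    results = {
        "cohort": cohort,
        "filtered": filtered,
        "exclusions": reports,
        "summaries": summaries,
        "contrasts": contrasts,
        "lcs_data": lcs_data,
        "lcs_fit": lcs_fit,
        "mediation_data": med_data,
        "mediation_fit": med_fit,
        "bias_shift": {"d_qsr": dqsr, "d_log_ratio": dlog, "table": shift_table},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "trials.csv", index=False)
        pd.DataFrame([asdict(r) for r in reports]).to_csv(out / "exclusions.csv", index=False)
        summaries.to_csv(out / "session_summary.csv", index=False)
        contrasts.to_csv(out / "group_contrasts.csv", index=False)
        _lcs_params_frame(lcs_fit).to_csv(out / "lcs_params.csv", index=False)
        with open(out / "mediation.json", "w") as fh:
            json.dump(_mediation_json(med_fit), fh, indent=2)
        shift_table.assign(mean_d_qsr=dqsr, mean_d_log_ratio=dlog).to_csv(
            out / "bias_shift.csv", index=False
        )
    return results


def _lcs_params_frame(fit) -> pd.DataFrame:
    rows = [
        dict(parameter=name, group=g, estimate=est, se=fit.se.get((name, g), np.nan))
        for (name, g), est in sorted(fit.params.items())
    ]
    frame = pd.DataFrame(rows)
    frame.attrs["chi_square"] = fit.chi_square
    return frame


def _mediation_json(fit) -> dict:
    def path(p):
        return {"estimate": p.estimate, "ci": list(p.ci), "p_boot": p.p_boot, "p_z": p.p_z}

    return {
        "a": path(fit.a),
        "b": path(fit.b),
        "c": path(fit.c),
        "c_prime": path(fit.c_prime),
        "ab": path(fit.ab),
        "n_boot": fit.n_boot,
    }
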