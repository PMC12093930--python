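"""Simulate -> measure -> aggregate -> report orchestration.

``run_study`` simulates synthetic cohorts of dyads (human-surrogate
pairs and human-machine pairs) across the three group conditions and
four workload levels, applies the exclusion filter, computes every
metric, and emits tidy tables, contrasts and a reproducibility
manifest.  ``analyze`` re-derives the same tables from logged trials
(or from flat CSV exports of external data via a column-mapping
adapter), so a report bundle is closed under re-analysis.

Statistical conventions: cell means are dyad-level (each dyad
contributes one value per cell before any averaging across dyads); the
separate condition collapses to one value per dyad — the mean of the
two players for human-human (HH) teams, the human member alone for
human-machine (HM) teams.  Contrast sign conventions are
"collaborative - competitive" and "HH - HM".  Omnibus mixed ANOVAs are
delegated to pingouin and reported alongside the bespoke contrasts.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .simulator import (GameConfig, DyadSpec, run_session, run_trial,
                        write_trial_log, read_trial_log, WORKLOAD_NAMES,
                        TEAM_CONDITIONS)
from .agents import (PolicySpec, build_policy, CalibrationTarget,
                     calibrate_policy, _policy_for_scalar)
from .metrics import (dyad_miss_table, dyad_capacity_table, behavior_metrics,
                      balls_maintained, exclusion_filter, miss_rate,
                      capacity_coefficient, UndefinedCellError)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def collapse_separate_units(miss_df: pd.DataFrame) -> pd.DataFrame:
    """One row per dyad cell: team-condition rows pass through, and the
    separate condition collapses its two player rows — averaged for HH
    dyads, the human member (player A) alone for HM dyads (machine solo
    rates are excluded from analysis)."""
    team = miss_df[miss_df.unit == "team"].copy()
    sep = miss_df[miss_df.condition == "separate"].copy()
    hh = sep[sep.team_type == "HH"].groupby(
        ["dyad_id", "team_type", "condition", "workload"], as_index=False,
        observed=True).agg(miss_rate=("miss_rate", "mean"))
    hm = sep[(sep.team_type == "HM") & (sep.unit == "A")][
        ["dyad_id", "team_type", "condition", "workload", "miss_rate"]]
    sep_collapsed = pd.concat([hh, hm], ignore_index=True)
    sep_collapsed["unit"] = "player"
    team = team[["dyad_id", "team_type", "condition", "workload", "unit",
                 "miss_rate"]]
    return pd.concat([team, sep_collapsed], ignore_index=True)


def aggregate(df: pd.DataFrame, value: str,
              by=("team_type", "condition", "workload")) -> pd.DataFrame:
    """Cell means/sds/ns of a dyad-level metric table.

    Empty cells are absent from the output (missing, never zero); a
    single-dyad cell reports ``sd = NaN``.
    """
    if value not in df.columns:
        raise ValueError(f"no column {value!r} in table")
    sub = df.dropna(subset=[value])
    out = (sub.groupby(list(by), as_index=False, observed=True)
              .agg(mean=(value, "mean"), sd=(value, "std"), n=(value, "size")))
    out.insert(len(by), "metric", value)
    return out


@dataclass(frozen=True)
class ContrastResult:
    """A focused two-cell comparison (paired or independent t)."""

    contrast_name: str
    mean_difference: float
    t_value: float
    df: float
    p_value: float
    design: str  # within | between
    n: int


def contrast(df: pd.DataFrame, value: str, cell_a: dict, cell_b: dict,
             design: str, name: str | None = None,
             unit_col: str = "dyad_id") -> ContrastResult:
    """Mean difference (cell_a - cell_b) with the matching t statistic.

    ``cell_a``/``cell_b`` are column->value filters selecting one cell
    each.  ``design="within"`` pairs observations on ``unit_col`` (the
    dyad) and uses a paired t; ``design="between"`` uses Welch's
    two-sample t.  Cells are first reduced to one value per unit.
    """
    if design not in ("within", "between"):
        raise ValueError("design must be 'within' or 'between'")

    def cell(filt):
        sub = df
        for col, val in filt.items():
            sub = sub[sub[col] == val]
        return sub.dropna(subset=[value]).groupby(unit_col, observed=True)[value].mean()

    a, b = cell(cell_a), cell(cell_b)
    if design == "within":
        common = a.index.intersection(b.index)
        if len(common) < 2:
            raise ValueError("paired contrast needs >= 2 complete dyads per cell")
        a, b = a.loc[common], b.loc[common]
        diff = a.to_numpy() - b.to_numpy()
        if np.isclose(diff.std(ddof=1), 0.0):
            # degenerate paired data: identical cells -> t = 0; a constant
            # nonzero shift has no within-pair variance -> unbounded t
            if np.allclose(diff, 0.0):
                t_val, p_val = 0.0, 1.0
            else:
                t_val, p_val = math.copysign(np.inf, diff.mean()), 0.0
        else:
            t_val, p_val = stats.ttest_rel(a, b)
        dof = len(common) - 1.0
        n = len(common)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("independent contrast needs >= 2 dyads per cell")
        res = stats.ttest_ind(a, b, equal_var=False)
        t_val, p_val = res.statistic, res.pvalue
        dof = float(res.df)
        n = len(a) + len(b)
    return ContrastResult(
        contrast_name=name or f"{cell_a} vs {cell_b}",
        mean_difference=float(a.mean() - b.mean()),
        t_value=float(t_val), df=float(dof), p_value=float(p_val),
        design=design, n=n)


def mixed_anova(df: pd.DataFrame, dv: str, within: str, between: str,
                subject: str = "dyad_id") -> pd.DataFrame:
    """Omnibus mixed ANOVA, delegated to pingouin (one within factor)."""
    import pingouin as pg
    return pg.mixed_anova(data=df, dv=dv, within=within, between=between,
                          subject=subject)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

# surrogate strategy biases used for synthetic human players: collaborative
# space-sharing and competitive opponent-monitoring, the two behavioural
# signatures the study reports for human dyads
HH_SURROGATE_BIASES = {"share_bias": 0.8, "monitor_weight": 0.35}


def default_arm_specs(noise_scalar: float = 1.0) -> dict:
    """Policy specs for the two study arms.

    The HH arm pairs two noisy human surrogates with the strategy
    biases enabled; the HM arm pairs one surrogate (player A, the
    human) with a considerate ideal observer at the same noise level.
    """
    from .agents import _NOISE_SCALE_PX, _LAPSE_SCALE, _LAPSE_DURATION_S
    noise = {"motor_noise_px": _NOISE_SCALE_PX * noise_scalar,
             "lapse_prob": min(1.0, _LAPSE_SCALE * noise_scalar),
             "lapse_duration_s": _LAPSE_DURATION_S}
    surrogate = {"kind": "human_surrogate",
                 "params": {**noise, **HH_SURROGATE_BIASES}}
    machine = {"kind": "ideal_observer_considerate", "params": dict(noise)}
    return {"HH": {"team_type": "HH", "policy_a": surrogate,
                   "policy_b": dict(surrogate)},
            "HM": {"team_type": "HM", "policy_a": surrogate,
                   "policy_b": machine}}


def simulate_cohort(arm: dict, n_dyads: int, config: GameConfig, seed: int,
                    record: str = "positions", arm_name: str = "") -> list:
    """Simulate ``n_dyads`` full 36-trial sessions for one arm."""
    rng = random.Random(seed)
    conditions = ("separate", "collaborative", "competitive")
    records = []
    for i in range(n_dyads):
        pol_a = build_policy(PolicySpec(**arm["policy_a"]))
        pol_b = build_policy(PolicySpec(**arm["policy_b"]))
        order = list(conditions)
        rng.shuffle(order)
        spec = DyadSpec(dyad_id=f"{arm_name or arm['team_type']}-{i:03d}",
                        team_type=arm["team_type"], policy_a=pol_a,
                        policy_b=pol_b, block_order=tuple(order),
                        agent_specs={"A": arm["policy_a"], "B": arm["policy_b"]})
        records.append(run_session(spec, config, rng.randrange(2 ** 31),
                                   record=record))
    return records


def dyad_summaries_for_exclusion(records) -> list:
    """Per-dyad human DRT accuracy and low-workload separate miss rate."""
    out = []
    for rec in records:
        humans = {}
        human_players = ("A", "B") if rec.team_type == "HH" else ("A",)
        for p in human_players:
            cell = [t for t in rec.trials
                    if t.condition == "separate" and t.workload == "low"]
            hits = sum(t.hits[p] for t in cell)
            misses = sum(t.misses[p] for t in cell)
            try:
                mr = miss_rate(hits, misses)
            except UndefinedCellError:
                mr = None
            accs = [t.drt[p]["accuracy"] for t in rec.trials
                    if p in t.drt and t.drt[p]["accuracy"] is not None]
            acc = float(np.mean(accs)) if accs else None
            humans[p] = {"drt_accuracy": acc, "low_separate_missrate": mr}
        out.append({"dyad_id": rec.dyad_id, "humans": humans})
    return out


# ---------------------------------------------------------------------------
# UCIP-null and limited-capacity synthetic dyads
# ---------------------------------------------------------------------------

def simulate_ucip_null_cohort(n_dyads: int, config: GameConfig, seed: int,
                              noise_scalar: float = 1.0,
                              penalty_odds: float = 1.0,
                              workloads=WORKLOAD_NAMES,
                              trials_per_cell: int = 1) -> pd.DataFrame:
    """Dyads of independent solo players with conjunctive team misses.

    Each synthetic dyad runs solo separate-condition trials for both
    members; the team outcome for the k-th terminated ball pairs the
    members' k-th outcomes and misses iff *both* members missed — the
    unlimited-capacity independent parallel (UCIP) mechanism, which has
    no member interaction, so E[C(p)] = 0.  ``penalty_odds > 1``
    injects an efficiency loss by multiplying the odds of the pooled
    conjunctive team miss rate and resampling extra team misses,
    driving C(p) below zero.

    Returns a tidy frame of (dyad_id, workload, pA, pB, pAB, C).
    """
    if penalty_odds < 1.0:
        raise ValueError("penalty_odds must be >= 1")
    rng = random.Random(seed)
    rows = []
    for d in range(n_dyads):
        pol_a = _policy_for_scalar("ideal_observer_simple", noise_scalar)
        pol_b = _policy_for_scalar("ideal_observer_simple", noise_scalar)
        for wl in workloads:
            out_a, out_b = [], []
            ha = ma = hb = mb = 0.0
            for _ in range(trials_per_cell):
                ta = run_trial(pol_a, None, "separate", wl, config,
                               rng.randrange(2 ** 31), record="none")
                tb = run_trial(pol_b, None, "separate", wl, config,
                               rng.randrange(2 ** 31), record="none")
                out_a += [1 if ev.kind == "miss" else 0 for ev in ta.events
                          if ev.kind in ("hit", "miss")]
                out_b += [1 if ev.kind == "miss" else 0 for ev in tb.events
                          if ev.kind in ("hit", "miss")]
                ha += ta.hits["A"]; ma += ta.misses["A"]
                hb += tb.hits["A"]; mb += tb.misses["A"]
            if ha + ma == 0 or hb + mb == 0:
                continue
            pA = miss_rate(ha, ma)
            pB = miss_rate(hb, mb)
            # pair each of A's ball outcomes with a random one of B's:
            # the members are independent, so any pairing is a valid
            # conjunction, and random pairing avoids aligning the two
            # members' within-trial structure (ball index effects)
            rng.shuffle(out_a)
            k = min(len(out_a), len(out_b))
            team = [a * b for a, b in zip(out_a[:k], out_b[:k])]
            if penalty_odds > 1.0 and team:
                q = sum(team) / len(team)
                if 0.0 < q < 1.0:
                    odds = q / (1.0 - q) * penalty_odds
                    q_target = odds / (1.0 + odds)
                    p_extra = (q_target - q) / (1.0 - q)
                    team = [m or (rng.random() < p_extra) for m in team]
            if not team:
                continue
            pAB = sum(team) / len(team)
            res = capacity_coefficient(pA, pB, pAB)
            rows.append({"dyad_id": f"null-{d:03d}", "workload": wl,
                         "pA": pA, "pB": pB, "pAB": pAB, "C": res.C,
                         "classification": res.classification})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Configuration of a synthetic study run."""

    n_dyads_per_arm: int = 10
    seed: int = 0
    noise_scalar: float | None = 1.0  # None -> calibrate first
    game: GameConfig = field(default_factory=GameConfig)
    record: str = "positions"
    write_trial_logs: bool = False
    arms: dict | None = None  # default_arm_specs() when None


@dataclass
class StudyReport:
    """All tables a study run produces, plus the manifest."""

    miss_rates: pd.DataFrame
    miss_aggregate: pd.DataFrame
    capacity: pd.DataFrame
    capacity_aggregate: pd.DataFrame
    balls: pd.DataFrame
    behavior: pd.DataFrame
    behavior_aggregate: pd.DataFrame
    contrasts: pd.DataFrame
    exclusions: dict
    manifest: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("miss_rates", "miss_aggregate", "capacity",
                     "capacity_aggregate", "balls", "behavior",
                     "behavior_aggregate", "contrasts"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        with open(out / "exclusions.json", "w") as fh:
            json.dump(self.exclusions, fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def _workload_count_of(config, wl):
    return config.workload_count(wl)


def balls_maintained_table(miss_collapsed: pd.DataFrame,
                           config: GameConfig) -> pd.DataFrame:
    """Balls-at-40% per dyad x condition from collapsed miss rates."""
    rows = []
    for (dyad, team_type, condition), grp in miss_collapsed.groupby(
            ["dyad_id", "team_type", "condition"], observed=True):
        if len(grp) != 4 or grp.miss_rate.isna().any():
            continue
        pts = [(config.workload_count(w), r)
               for w, r in zip(grp.workload, grp.miss_rate)]
        try:
            bm = balls_maintained(pts)
        except (ValueError, UndefinedCellError):
            continue
        rows.append({"dyad_id": dyad, "team_type": team_type,
                     "condition": condition,
                     "n_balls_at_40": bm.n_balls_at_criterion,
                     "crossing_valid": bm.crossing_valid})
    return pd.DataFrame(rows)


def analyze_records(records, config: GameConfig) -> dict:
    """Metric tables from a list of DyadRecords (the measurement stage)."""
    miss = pd.concat([dyad_miss_table(r) for r in records], ignore_index=True)
    capacity = pd.concat([dyad_capacity_table(r) for r in records],
                         ignore_index=True)
    collapsed = collapse_separate_units(miss)
    balls = balls_maintained_table(collapsed, config)
    behav_rows = []
    for rec in records:
        for t in rec.trials:
            if t.condition == "separate" or t.xA is None or t.xB is None:
                continue
            bm = behavior_metrics(t, tick_rate=config.tick_rate)
            behav_rows.append({"dyad_id": rec.dyad_id,
                               "team_type": rec.team_type,
                               "condition": t.condition,
                               "workload": t.workload,
                               "trial_id": t.trial_id,
                               "momentary_distance": bm.momentary_distance,
                               "hcs_proportion": bm.hcs_proportion})
    behavior = pd.DataFrame(behav_rows)
    return {"miss": miss, "miss_collapsed": collapsed, "capacity": capacity,
            "balls": balls, "behavior": behavior}


def standard_contrasts(collapsed: pd.DataFrame,
                       capacity: pd.DataFrame) -> pd.DataFrame:
    """The study's headline contrasts, where the cells have enough dyads.

    Sign conventions: collaborative - competitive, HH - HM.
    """
    out = []

    def attempt(fn, *args, **kw):
        try:
            out.append(asdict(fn(*args, **kw)))
        except (ValueError, KeyError):
            pass

    team_rows = collapsed[collapsed.unit == "team"]
    attempt(contrast, team_rows, "miss_rate",
            {"team_type": "HH"}, {"team_type": "HM"}, "between",
            name="miss_rate: HH - HM (team conditions)")
    for tt in ("HH", "HM"):
        attempt(contrast, team_rows[team_rows.team_type == tt], "miss_rate",
                {"condition": "collaborative"}, {"condition": "competitive"},
                "within", name=f"miss_rate: collaborative - competitive ({tt})")
        attempt(contrast, capacity[capacity.team_type == tt], "C",
                {"condition": "collaborative"}, {"condition": "competitive"},
                "within", name=f"C(p): collaborative - competitive ({tt})")
    attempt(contrast, capacity, "C",
            {"team_type": "HH"}, {"team_type": "HM"}, "between",
            name="C(p): HH - HM")
    return pd.DataFrame(out)


def run_study(study: StudyConfig, out_dir=None) -> StudyReport:
    """End-to-end synthetic study: simulate, exclude, measure, report.

    Deterministic given ``study.seed``.  When ``out_dir`` is given the
    tables, manifest and (optionally) per-trial JSON-Lines logs are
    written there.
    """
    rng = random.Random(study.seed)
    config = study.game
    noise = study.noise_scalar
    if noise is None:
        cal = calibrate_policy("ideal_observer_simple", CalibrationTarget(),
                               config, seed=rng.randrange(2 ** 31))
        noise = cal.noise_scalar
    arms = study.arms if study.arms is not None else default_arm_specs(noise)

    records = []
    for arm_name, arm in arms.items():
        records += simulate_cohort(arm, study.n_dyads_per_arm, config,
                                   rng.randrange(2 ** 31), record=study.record,
                                   arm_name=arm_name)

    report = analyze_from_records(records, config)
    manifest = {
        "seed": study.seed, "n_dyads_per_arm": study.n_dyads_per_arm,
        "noise_scalar": noise, "config_digest": config.digest(),
        "arms": arms, "software_version": _pkg_version,
        "n_dyads_simulated": len(records),
    }
    report.manifest.update(manifest)

    if out_dir is not None:
        report.save(out_dir)
        if study.write_trial_logs:
            log_dir = Path(out_dir) / "trial_logs"
            log_dir.mkdir(exist_ok=True)
            for rec in records:
                d = log_dir / rec.dyad_id
                d.mkdir(exist_ok=True)
                meta = {"dyad_id": rec.dyad_id, "team_type": rec.team_type,
                        "block_order": list(rec.block_order),
                        "seed": rec.seed}
                with open(d / "dyad.json", "w") as fh:
                    json.dump(meta, fh)
                for t in rec.trials:
                    write_trial_log(t, d / f"{t.trial_id}.jsonl",
                                    tick_rate=config.tick_rate)
    return report


def analyze_from_records(records, config: GameConfig) -> StudyReport:
    """Measurement + aggregation + contrasts for simulated records."""
    summaries = dyad_summaries_for_exclusion(records)
    excl = exclusion_filter(summaries)
    kept = [r for r in records if r.dyad_id in set(excl.retained)]
    tables = analyze_records(kept, config) if kept else None
    if tables is None or tables["miss"].empty:
        empty = pd.DataFrame()
        return StudyReport(empty, empty, empty, empty, empty, empty, empty,
                           empty, {"excluded": excl.excluded,
                                   "retained": excl.retained}, {})
    collapsed = tables["miss_collapsed"]
    capacity = tables["capacity"]
    behavior = tables["behavior"]
    return StudyReport(
        miss_rates=collapsed,
        miss_aggregate=aggregate(collapsed, "miss_rate"),
        capacity=capacity,
        capacity_aggregate=aggregate(capacity, "C"),
        balls=tables["balls"],
        behavior=behavior,
        behavior_aggregate=(aggregate(behavior, "momentary_distance")
                            if not behavior.empty else pd.DataFrame()),
        contrasts=standard_contrasts(collapsed, capacity),
        exclusions={"excluded": excl.excluded, "retained": excl.retained},
        manifest={})


# ---------------------------------------------------------------------------
# external-data adapter (flat CSV with a user-supplied column mapping)
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ("dyad", "team_type", "condition", "workload", "trial",
                  "unit", "hits", "misses")


def load_counts_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load a flat per-trial hit/miss count table.

    ``column_map`` maps the standard column names
    (dyad, team_type, condition, workload, trial, unit, hits, misses)
    to the columns of the deposited file; identity when omitted.
    """
    df = pd.read_csv(path)
    cmap = {std: (column_map or {}).get(std, std) for std in _COUNT_COLUMNS}
    missing = [src for src in cmap.values() if src not in df.columns]
    if missing:
        raise ValueError(f"counts file lacks columns: {missing}")
    out = df[[cmap[s] for s in _COUNT_COLUMNS]].copy()
    out.columns = _COUNT_COLUMNS
    return out


def analyze_counts(counts: pd.DataFrame, config: GameConfig | None = None
                   ) -> dict:
    """Miss-rate, capacity and balls tables from a flat count table.

    The same measurement rules as for simulated sessions: counts pooled
    per (dyad, condition, workload, unit); units 'A'/'B' in the
    separate condition, 'team' in team conditions.
    """
    config = config or GameConfig()
    pooled = (counts.groupby(["dyad", "team_type", "condition", "workload",
                              "unit"], as_index=False, observed=True)
                    .agg(hits=("hits", "sum"), misses=("misses", "sum")))
    pooled["miss_rate"] = [
        np.nan if h + m == 0 else 1.0 - h / (h + m)
        for h, m in zip(pooled.hits, pooled.misses)]
    miss = pooled.rename(columns={"dyad": "dyad_id"})
    sep = miss[miss.condition == "separate"].set_index(
        ["dyad_id", "unit", "workload"])
    rows = []
    for (dyad, tt, condition, wl), grp in miss[
            (miss.unit == "team")
            & miss.condition.isin(TEAM_CONDITIONS)].groupby(
            ["dyad_id", "team_type", "condition", "workload"], observed=True):
        try:
            pA = float(sep.loc[(dyad, "A", wl), "miss_rate"])
            pB = float(sep.loc[(dyad, "B", wl), "miss_rate"])
        except KeyError:
            continue
        pAB = float(grp.miss_rate.iloc[0])
        if any(np.isnan(v) for v in (pA, pB, pAB)):
            continue
        res = capacity_coefficient(pA, pB, pAB)
        rows.append({"dyad_id": dyad, "team_type": tt, "condition": condition,
                     "workload": wl, "pA": pA, "pB": pB, "pAB": pAB,
                     "C": res.C, "classification": res.classification})
    capacity = pd.DataFrame(rows)
    collapsed = collapse_separate_units(miss)
    balls = balls_maintained_table(collapsed, config)
    return {"miss": miss, "miss_collapsed": collapsed,
            "capacity": capacity, "balls": balls}


def analyze(in_dir, config: GameConfig | None = None) -> StudyReport:
    """Re-derive a report bundle from logged trials in ``in_dir``.

    ``in_dir`` must contain ``trial_logs/<dyad_id>/`` directories as
    written by :func:`run_study` (a ``dyad.json`` plus one JSON-Lines
    file per trial).
    """
    from .simulator import DyadRecord
    config = config or GameConfig()
    log_root = Path(in_dir) / "trial_logs"
    if not log_root.is_dir():
        raise FileNotFoundError(f"no trial_logs directory under {in_dir}")
    records = []
    for d in sorted(log_root.iterdir()):
        meta_path = d / "dyad.json"
        if not meta_path.exists():
            continue
        with open(meta_path) as fh:
            meta = json.load(fh)
        trials = [read_trial_log(p) for p in sorted(d.glob("*.jsonl"))]
        records.append(DyadRecord(
            dyad_id=meta["dyad_id"], team_type=meta["team_type"],
            block_order=tuple(meta["block_order"]), trials=trials,
            agent_specs={}, seed=meta["seed"]))
    return analyze_from_records(records, config)
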