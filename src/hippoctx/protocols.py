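"""Behavioral protocols: performance metric, criterion training, experiments.

Retrieval performance on each trial is scored from the root-mean-squared error
E between the recalled reward field and the target odor code,

    P(%) = max(50, 100 * (1 - E)^10 / (10 * 0.5^10 + (1 - E)^10)),

which floors chance at 50% (a two-alternative choice) and approaches ~99% for
perfect recall.  A block presents every problem in a list once, in random
order; the learning criterion is a block-mean P of at least 90% in two
consecutive blocks.

The module implements the five simulated inactivation experiments:

* ``run_navawongse``: two conflicting lists in contexts A and B trained to
  criterion, then test blocks per context with and without PFC inactivation.
* ``run_p1a``: concurrent acquisition of eight problems to criterion (muscimol
  group inactivated for training blocks 1-3) followed by four test blocks with
  the control group inactivated on test blocks 1-3.
* ``run_p1b``: ten problems acquired one at a time to criterion (muscimol
  group inactivated throughout training).
* ``run_p2``: 2x2 design (inactivation x same/different context) for acquiring
  a conflicting List 2 after List 1, with interference index and
  perseverative/non-perseverative error taxonomy.
* ``run_p3``: five blocks of List 1 (muscimol inactivated on blocks 1-3) then
  five blocks of conflicting List 2 in the same context under normal operation.

``run_prediction_variants`` reruns 1A and 3 without lifetime pre-training and
sweeps DG sparsity, probing which effects require a storehouse of prior
conflicting memories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import Network, NetworkConfig, TrialInput, build_network
from .stimuli import (
    DiscriminationProblem,
    ExperimentStimuli,
    ProblemList,
    block_order,
    make_experiment_stimuli,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "SimRat",
    "performance_from_rmse",
    "rmse",
    "choose",
    "classify_error",
    "find_criterion_block",
    "run_to_criterion",
    "run_navawongse",
    "run_p1a",
    "run_p1b",
    "run_p2",
    "run_p3",
    "run_prediction_variants",
    "interference_index",
    "summarize",
    "welch_t",
]

CHANCE_DENOM = 10.0 * 0.5 ** 10


def performance_from_rmse(E: float | np.ndarray) -> float | np.ndarray:
    """Map recall error E in [0, 1] to percent performance, floored at chance."""
    E = np.asarray(E, dtype=float)
    if np.any((E < 0) | (E > 1)):
        raise ValueError("E must lie in [0, 1]")
    raw = 100.0 * (1.0 - E) ** 10 / (CHANCE_DENOM + (1.0 - E) ** 10)
    out = np.maximum(50.0, raw)
    return float(out) if out.ndim == 0 else out


def rmse(r_out: np.ndarray, r_targ: np.ndarray) -> float:
    """Root-mean-squared error between recalled and target reward patterns."""
    r_out = np.asarray(r_out, dtype=float)
    r_targ = np.asarray(r_targ, dtype=float)
    if r_out.shape != r_targ.shape:
        raise ValueError("pattern length mismatch")
    return float(np.sqrt(np.mean((r_out - r_targ) ** 2)))


def choose(
    r_out: np.ndarray,
    problem: DiscriminationProblem,
    rng: np.random.Generator,
) -> str:
    """Discrete choice: the pair member whose code is nearest the recall.

    Ties are broken uniformly at random from the trial's RNG stream.
    """
    e0 = rmse(r_out, problem.odor_pair[0].vector)
    e1 = rmse(r_out, problem.odor_pair[1].vector)
    if e0 == e1:
        return problem.odor_pair[int(rng.integers(0, 2))].label
    return problem.odor_pair[0].label if e0 < e1 else problem.odor_pair[1].label


def classify_error(
    problem: DiscriminationProblem,
    choice: str,
    list1_rewarded: dict[str, bool],
) -> str:
    """Taxonomy of incorrect List-2 choices.

    Perseverative: the chosen odor was rewarded in List 1 and is unrewarded in
    List 2 (the old contingency persists).  Non-perseverative: a novel List-2
    odor is chosen when paired with an odor that was unrewarded in List 1.
    """
    if choice == problem.rewarded_odor.label:
        raise ValueError("classify_error called on a correct trial")
    if choice in list1_rewarded and list1_rewarded[choice]:
        return "perseverative"
    retained = [o.label for o in problem.odor_pair if o.label in list1_rewarded]
    if choice not in list1_rewarded and retained and not list1_rewarded[retained[0]]:
        return "non_perseverative"
    # incorrect choice outside the standard two-category taxonomy (does not arise under
    # the standard List-2 construction)
    return "other"


def find_criterion_block(
    block_means: list[float], pct: float = 90.0, consecutive: int = 2
) -> int | None:
    """First block at which the last ``consecutive`` block means all reach ``pct``.

    Returns the 1-based index of the block completing the run, or None.
    """
    streak = 0
    for i, m in enumerate(block_means, start=1):
        streak = streak + 1 if m >= pct else 0
        if streak >= consecutive:
            return i
    return None


@dataclass
class ExperimentConfig:
    """Group sizes, schedules and toggles shared by the experiment runners."""

    n_per_group: int = 10
    criterion_pct: float = 90.0
    criterion_consecutive: int = 2
    max_blocks: int = 50
    pretraining: bool = True
    pretrain_blocks: int = 10
    n_problems: int = 8
    n_blocked_problems: int = 10
    blocked_block_size: int = 4
    test_blocks: int = 4
    inactivated_blocks: tuple[int, ...] = (1, 2, 3)  # 1-based block indices
    dg_kwta: float | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def network_config(self) -> NetworkConfig:
        cfg = self.network
        if self.dg_kwta is not None:
            cfg = replace(cfg, kwta_dg=self.dg_kwta)
        return cfg


@dataclass
class ExperimentResult:
    experiment: str
    trials: pd.DataFrame
    summary: dict


class SimRat:
    """One simulated animal: a fresh network, stimuli and behavioral RNG."""

    def __init__(
        self,
        rat_id: int,
        group: str,
        seed_seq: np.random.SeedSequence,
        cfg: ExperimentConfig,
    ) -> None:
        self.rat_id = rat_id
        self.group = group
        self.cfg = cfg
        s_net, s_stim, s_beh = seed_seq.spawn(3)
        self.net: Network = build_network(cfg.network_config(), s_net)
        self.stim: ExperimentStimuli = make_experiment_stimuli(
            np.random.default_rng(s_stim),
            n_problems=cfg.n_problems,
            n_blocked=cfg.n_blocked_problems,
        )
        self.rng = np.random.default_rng(s_beh)
        self.records: list[dict] = []

    # -- single trial -------------------------------------------------------

    def run_problem(
        self,
        problem: DiscriminationProblem,
        *,
        phase_name: str,
        block: int,
        mode: str,
        inactivated: bool,
        context: str,
        learn: bool = True,
    ) -> dict:
        if inactivated:
            self.net.set_pfc_inactivated()
        else:
            self.net.set_context(context)
        trial = TrialInput(
            x_pattern=problem.odor_pair[0].vector,
            y_pattern=problem.odor_pair[1].vector,
            r_target=problem.rewarded_odor.vector,
            mode=mode,
        )
        res = self.net.run_trial(trial, learn=learn and mode == "encode")
        E = rmse(res.r_out, problem.rewarded_odor.vector)
        P = performance_from_rmse(E)
        choice = choose(res.r_out, problem, self.rng)
        rec = {
            "rat": self.rat_id,
            "group": self.group,
            "context": "none" if inactivated else context,
            "inactivated": inactivated,
            "phase": phase_name,
            "block": block,
            "problem": problem.index,
            "mode": mode,
            "rmse": E,
            "perf": P,
            "choice": choice,
            "correct": choice == problem.rewarded_odor.label,
            "error_type": "none",
            "dg_active": res.dg_active,
        }
        self.records.append(rec)
        return rec

    # -- blocks -------------------------------------------------------------

    def run_block(
        self,
        problems: ProblemList,
        *,
        phase_name: str,
        block: int,
        mode: str = "encode",
        inactivated: bool = False,
        context: str = "A",
        learn: bool = True,
    ) -> float:
        """One block: each problem once in random order; returns mean P."""
        perfs = [
            self.run_problem(
                p,
                phase_name=phase_name,
                block=block,
                mode=mode,
                inactivated=inactivated,
                context=context,
                learn=learn,
            )["perf"]
            for p in block_order(self.rng, problems)
        ]
        return float(np.mean(perfs))

    def run_to_criterion(
        self,
        problems: ProblemList,
        *,
        phase_name: str,
        context: str,
        inactivated_blocks: tuple[int, ...] = (),
        min_blocks: int = 0,
    ) -> int | None:
        """Encode blocks until block-mean P >= criterion twice in a row.

        ``inactivated_blocks`` are 1-based block indices run under PFC
        inactivation.  Returns the criterion block index (the second
        qualifying block) or None if ``max_blocks`` is hit first.
        """
        cfg = self.cfg
        streak = 0
        criterion_block: int | None = None
        for block in range(1, cfg.max_blocks + 1):
            mean_p = self.run_block(
                problems,
                phase_name=phase_name,
                block=block,
                inactivated=block in inactivated_blocks,
                context=context,
            )
            streak = streak + 1 if mean_p >= cfg.criterion_pct else 0
            if streak >= cfg.criterion_consecutive and criterion_block is None:
                criterion_block = block
            if criterion_block is not None and block >= min_blocks:
                return criterion_block
        return criterion_block

    def pretrain(self) -> None:
        """Lifetime pre-training: conflicting lists in contexts C and D."""
        cfg = self.cfg
        for problems, ctx in ((self.stim.pretrain_c, "C"), (self.stim.pretrain_d, "D")):
            for block in range(1, cfg.pretrain_blocks + 1):
                self.run_block(
                    problems,
                    phase_name=f"pretrain_{ctx.lower()}",
                    block=block,
                    context=ctx,
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def run_to_criterion(
    rat: SimRat,
    problems: ProblemList,
    *,
    phase_name: str = "train",
    context: str = "A",
    inactivated_blocks: tuple[int, ...] = (),
) -> int | None:
    """Functional wrapper around :meth:`SimRat.run_to_criterion`."""
    return rat.run_to_criterion(
        problems,
        phase_name=phase_name,
        context=context,
        inactivated_blocks=inactivated_blocks,
    )


def _spawn_rats(
    seed: int | np.random.SeedSequence,
    groups: dict[str, int],
    cfg: ExperimentConfig,
) -> list[SimRat]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    total = sum(groups.values())
    children = ss.spawn(total)
    rats = []
    i = 0
    for group, n in groups.items():
        for _ in range(n):
            rats.append(SimRat(i, group, children[i], cfg))
            i += 1
    return rats


def _collect(experiment: str, rats: list[SimRat], summary: dict) -> ExperimentResult:
    trials = pd.concat([r.to_frame() for r in rats], ignore_index=True)
    return ExperimentResult(experiment=experiment, trials=trials, summary=summary)


# ---------------------------------------------------------------------------
# experiment protocols
# ---------------------------------------------------------------------------


def run_navawongse(
    cfg: ExperimentConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    test_blocks_per_condition: int = 2,
) -> ExperimentResult:
    """Context-guided retrieval of two conflicting lists, with/without PFC.

    A single group of rats learns List 1 in context A and its reversal in
    context B, both to criterion, then runs test blocks in each context under
    the control (saline) and inactivated (muscimol) conditions, learning off.
    """
    cfg = cfg or ExperimentConfig()
    rats = _spawn_rats(seed, {"all": cfg.n_per_group}, cfg)
    for rat in rats:
        if cfg.pretraining:
            rat.pretrain()
        rat.run_to_criterion(rat.stim.list1, phase_name="train_A", context="A")
        rat.run_to_criterion(rat.stim.list1_reversed, phase_name="train_B", context="B")
        for condition, inact in (("saline", False), ("muscimol", True)):
            for context, problems in (("A", rat.stim.list1), ("B", rat.stim.list1_reversed)):
                for block in range(1, test_blocks_per_condition + 1):
                    rat.run_block(
                        problems,
                        phase_name=f"test_{condition}",
                        block=block,
                        mode="test",
                        inactivated=inact,
                        context=context,
                        learn=False,
                    )
    trials = pd.concat([r.to_frame() for r in rats], ignore_index=True)
    test = trials[trials["mode"] == "test"]
    per_rat = test.groupby([test["phase"], test["rat"]])["perf"].mean().unstack(0)
    tt = stats.ttest_rel(per_rat["test_saline"], per_rat["test_muscimol"])
    summary = {
        "saline_mean": float(per_rat["test_saline"].mean()),
        "muscimol_mean": float(per_rat["test_muscimol"].mean()),
        "paired_t": float(tt.statistic),
        "paired_p": float(tt.pvalue),
    }
    return ExperimentResult("navawongse", trials, summary)


def run_p1a(
    cfg: ExperimentConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ExperimentResult:
    """Concurrent acquisition to criterion plus four retrieval test blocks.

    The muscimol group trains under inactivation for blocks 1-3; after
    criterion, the saline group is tested under inactivation for test blocks
    1-3 and recovers on block 4.
    """
    cfg = cfg or ExperimentConfig()
    rats = _spawn_rats(seed, {"saline": cfg.n_per_group, "muscimol": cfg.n_per_group}, cfg)
    criterion_blocks = {}
    for rat in rats:
        if cfg.pretraining:
            rat.pretrain()
        inact = cfg.inactivated_blocks if rat.group == "muscimol" else ()
        cr = rat.run_to_criterion(
            rat.stim.list1, phase_name="train", context="A", inactivated_blocks=inact
        )
        criterion_blocks[rat.rat_id] = cr
        for block in range(1, cfg.test_blocks + 1):
            test_inact = rat.group == "saline" and block in cfg.inactivated_blocks
            rat.run_block(
                rat.stim.list1,
                phase_name="test",
                block=block,
                mode="test",
                inactivated=test_inact,
                context="A",
                learn=False,
            )
    trials = pd.concat([r.to_frame() for r in rats], ignore_index=True)
    test = trials[(trials["phase"] == "test") & (trials["block"] <= 3)]
    group_means = test.groupby("group")["perf"].mean()
    summary = {
        "criterion_blocks": criterion_blocks,
        "test_drop": float(group_means["muscimol"] - group_means["saline"]),
        "test_saline_mean": float(group_means["saline"]),
        "test_muscimol_mean": float(group_means["muscimol"]),
    }
    return ExperimentResult("p1a", trials, summary)


def run_p1b(
    cfg: ExperimentConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ExperimentResult:
    """Blocked acquisition: one problem at a time to criterion.

    Blocks are ``blocked_block_size`` consecutive trials of the single problem;
    the muscimol group trains entirely under inactivation.
    """
    cfg = cfg or ExperimentConfig()
    rats = _spawn_rats(seed, {"saline": cfg.n_per_group, "muscimol": cfg.n_per_group}, cfg)
    rows = []
    for rat in rats:
        if cfg.pretraining:
            rat.pretrain()
        order = rat.rng.permutation(len(rat.stim.blocked))
        for prob_idx in order:
            problem = rat.stim.blocked[int(prob_idx)]
            single = ProblemList(
                f"blocked_{prob_idx}", [problem] * cfg.blocked_block_size
            )
            cr = rat.run_to_criterion(
                single,
                phase_name=f"blocked_{prob_idx}",
                context="A",
                inactivated_blocks=(
                    tuple(range(1, cfg.max_blocks + 1))
                    if rat.group == "muscimol"
                    else ()
                ),
            )
            blocks_used = cr if cr is not None else cfg.max_blocks
            rows.append(
                {
                    "rat": rat.rat_id,
                    "group": rat.group,
                    "problem": int(prob_idx),
                    "trials_to_criterion": blocks_used * cfg.blocked_block_size,
                    "reached": cr is not None,
                }
            )
    trials = pd.concat([r.to_frame() for r in rats], ignore_index=True)
    per_problem = pd.DataFrame(rows)
    # best/worst halves by per-rat learning difficulty
    halves = []
    for rat_id, sub in per_problem.groupby("rat"):
        ranked = sub.sort_values("trials_to_criterion")
        n_half = len(ranked) // 2
        halves.append(
            {
                "rat": rat_id,
                "group": ranked["group"].iloc[0],
                "best_half": float(ranked["trials_to_criterion"].iloc[:n_half].mean()),
                "worst_half": float(ranked["trials_to_criterion"].iloc[-n_half:].mean()),
            }
        )
    halves = pd.DataFrame(halves)
    ttc = per_problem.groupby(["group", "rat"])["trials_to_criterion"].mean().unstack(0)
    tt = stats.ttest_ind(ttc["saline"], ttc["muscimol"], equal_var=False)
    summary = {
        "per_problem": per_problem,
        "halves": halves,
        "ttc_saline": float(ttc["saline"].mean()),
        "ttc_muscimol": float(ttc["muscimol"].mean()),
        "ttc_t": float(tt.statistic),
        "ttc_p": float(tt.pvalue),
    }
    return ExperimentResult("p1b", trials, summary)


def run_p2(
    cfg: ExperimentConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ExperimentResult:
    """2x2 conflicting-list acquisition: inactivation x same/different context.

    All four groups first learn List 1 in context A to criterion (at least
    five blocks, so the interference index is defined), then five blocks of the
    conflicting List 2 in context A (same) or B (different); muscimol groups
    are inactivated for List-2 blocks 1-3.
    """
    cfg = cfg or ExperimentConfig()
    groups = {
        "saline_same": cfg.n_per_group,
        "saline_diff": cfg.n_per_group,
        "muscimol_same": cfg.n_per_group,
        "muscimol_diff": cfg.n_per_group,
    }
    rats = _spawn_rats(seed, groups, cfg)
    error_rows = []
    for rat in rats:
        if cfg.pretraining:
            rat.pretrain()
        rat.run_to_criterion(
            rat.stim.list1, phase_name="list1", context="A", min_blocks=5
        )
        same = rat.group.endswith("same")
        problems = rat.stim.list2_same if same else rat.stim.list2_diff
        context = "A" if same else "B"
        muscimol = rat.group.startswith("muscimol")
        list1_rewarded = {
            p.rewarded_odor.label: True for p in rat.stim.list1
        } | {p.unrewarded_odor.label: False for p in rat.stim.list1}
        for block in range(1, 6):
            inact = muscimol and block in cfg.inactivated_blocks
            for problem in block_order(rat.rng, problems):
                rec = rat.run_problem(
                    problem,
                    phase_name="list2",
                    block=block,
                    mode="encode",
                    inactivated=inact,
                    context=context,
                )
                if not rec["correct"]:
                    etype = classify_error(problem, rec["choice"], list1_rewarded)
                    rec["error_type"] = etype
                    error_rows.append(
                        {"rat": rat.rat_id, "group": rat.group, "error_type": etype}
                    )
    trials = pd.concat([r.to_frame() for r in rats], ignore_index=True)
    idx = interference_index(trials)
    errors = pd.DataFrame(error_rows)
    summary = {
        "interference_index": idx,
        "errors": errors,
    }
    return ExperimentResult("p2", trials, summary)


def run_p3(
    cfg: ExperimentConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> ExperimentResult:
    """Five blocks of List 1 (muscimol inactivated blocks 1-3), then five
    blocks of the conflicting List 2 in the same context under normal PFC."""
    cfg = cfg or ExperimentConfig()
    rats = _spawn_rats(seed, {"saline": cfg.n_per_group, "muscimol": cfg.n_per_group}, cfg)
    for rat in rats:
        if cfg.pretraining:
            rat.pretrain()
        inact_blocks = cfg.inactivated_blocks if rat.group == "muscimol" else ()
        for block in range(1, 6):
            rat.run_block(
                rat.stim.list1,
                phase_name="list1",
                block=block,
                inactivated=block in inact_blocks,
                context="A",
            )
        for block in range(1, 6):
            rat.run_block(
                rat.stim.list2_same,
                phase_name="list2",
                block=block,
                inactivated=False,
                context="A",
            )
    trials = pd.concat([r.to_frame() for r in rats], ignore_index=True)

    def group_block_means(phase: str) -> pd.DataFrame:
        sub = trials[trials["phase"] == phase]
        return sub.groupby(["group", "block"])["perf"].mean().unstack(0)

    summary = {
        "list1_block_means": group_block_means("list1"),
        "list2_block_means": group_block_means("list2"),
    }
    return ExperimentResult("p3", trials, summary)


def interference_index(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-rat List 2 minus List 1 mean percent performance, first five blocks.

    More negative values mean stronger proactive interference from List 1.
    """
    sub = trials[trials["phase"].isin(["list1", "list2"]) & (trials["block"] <= 5)]
    counts = sub.groupby(["rat", "phase"])["block"].nunique().unstack("phase")
    if counts.min().min() < 5:
        raise ValueError("interference index requires five blocks on each list")
    means = sub.groupby(["rat", "group", "phase"])["perf"].mean().unstack("phase")
    means["interference_index"] = means["list2"] - means["list1"]
    return means.reset_index()


def run_prediction_variants(
    cfg: ExperimentConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    dg_kwta_levels: tuple[float, ...] = (0.01, 0.10, 0.25),
) -> dict[str, ExperimentResult]:
    """No-pretraining variants of 1A and 3, plus a DG-sparsity sweep of 3."""
    cfg = cfg or ExperimentConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s1a, s3 = ss.spawn(2)
    no_pre = replace(cfg, pretraining=False)
    out: dict[str, ExperimentResult] = {
        "p1a_no_pretrain": run_p1a(no_pre, s1a),
    }
    sweep_seeds = ss.spawn(len(dg_kwta_levels))
    for level, s in zip(dg_kwta_levels, sweep_seeds):
        res = run_p3(replace(no_pre, dg_kwta=level), s)
        out[f"p3_no_pretrain_k{int(round(level * 100))}"] = res
    return out


# ---------------------------------------------------------------------------
# summaries and statistics
# ---------------------------------------------------------------------------


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def summarize(result: ExperimentResult) -> dict[str, pd.DataFrame]:
    """Per-block group mean and SEM tables, one per protocol phase."""
    trials = result.trials
    tables = {}
    for phase, sub in trials.groupby("phase"):
        grp = sub.groupby(["group", "block"])["perf"]
        tables[str(phase)] = pd.DataFrame(
            {"mean": grp.mean(), "sem": grp.sem()}
        ).reset_index()
    return tables


def anova_inactivation_by_block(
    trials: pd.DataFrame, phase: str, blocks: tuple[int, ...] = (1, 2, 3)
) -> pd.DataFrame:
    """Two-way ANOVA (group x block) on block-level performance, via statsmodels."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = trials[(trials["phase"] == phase) & trials["block"].isin(blocks)]
    data = (
        sub.groupby(["rat", "group", "block"])["perf"].mean().reset_index()
    )
    model = smf.ols("perf ~ C(group) * C(block)", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)
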