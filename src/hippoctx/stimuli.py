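"""Synthetic odor stimuli and discrimination-problem lists.

Each odor is a random binary code on a 6x4 grid with exactly six cells on.
A discrimination problem pairs two odors, one of which hides the reward; a
problem list is the set a simulated rat works through once per block, in a
fresh random order each block.

The generator reproduces the standard list structure of the contextual odor
discrimination experiments:

* List 1:        {X_i, Y_i} -> X_i or Y_i (random baited side, fixed per problem)
* pretrain C:    {X_i, Z_i} -> X_i/Z_i     (shares X_i with List 1)
* pretrain D:    {Z_i, Y_i} -> Z_i/Y_i     (shares Y_i with List 1)
* reversal list: same pairs {X_i, Y_i} with the opposite odor baited
* List 2:        keeps one randomly retained odor of each List-1 pair, pairs it
                 with a novel odor W_i, and reverses the retained odor's
                 reward status.

The two pre-training lists emulate a lifetime of earlier experiences whose
components overlap with the experimental lists, acquired in two extra contexts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OdorPattern",
    "DiscriminationProblem",
    "ProblemList",
    "ExperimentStimuli",
    "make_odor",
    "make_experiment_stimuli",
    "block_order",
]

GRID_CELLS = 24
ACTIVE_CELLS = 6


@dataclass(frozen=True)
class OdorPattern:
    """A 24-cell binary odor code with exactly six active cells."""

    label: str
    code: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.code) != GRID_CELLS or sum(self.code) != ACTIVE_CELLS:
            raise ValueError("odor code must be 24 cells with exactly 6 on")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.code, dtype=float)


@dataclass(frozen=True)
class DiscriminationProblem:
    """An odor pair with a baited side and the context it belongs to."""

    odor_pair: tuple[OdorPattern, OdorPattern]
    rewarded: int  # index into odor_pair
    context: str
    index: int = 0

    def __post_init__(self) -> None:
        if self.rewarded not in (0, 1):
            raise ValueError("rewarded must be 0 or 1")
        if self.odor_pair[0].label == self.odor_pair[1].label:
            raise ValueError("the two odors must differ")

    @property
    def rewarded_odor(self) -> OdorPattern:
        return self.odor_pair[self.rewarded]

    @property
    def unrewarded_odor(self) -> OdorPattern:
        return self.odor_pair[1 - self.rewarded]


@dataclass
class ProblemList:
    list_id: str
    problems: list[DiscriminationProblem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.problems)

    def __iter__(self):
        return iter(self.problems)

    def __getitem__(self, i: int) -> DiscriminationProblem:
        return self.problems[i]


@dataclass
class ExperimentStimuli:
    """All lists one simulated rat needs, drawn from a single seed."""

    list1: ProblemList
    list1_reversed: ProblemList  # same pairs, opposite baited side (context B)
    list2_same: ProblemList     # overlap-of-one conflict list, same context A
    list2_diff: ProblemList     # same problems tagged for context B
    pretrain_c: ProblemList
    pretrain_d: ProblemList
    blocked: ProblemList        # 10 single problems for one-at-a-time training

    def to_json(self) -> str:
        def enc_list(pl: ProblemList) -> list:
            return [
                {
                    "pair": [
                        {"label": o.label, "code": list(o.code)}
                        for o in p.odor_pair
                    ],
                    "rewarded": p.rewarded,
                    "context": p.context,
                    "index": p.index,
                }
                for p in pl
            ]

        return json.dumps(
            {name: enc_list(getattr(self, name)) for name in (
                "list1", "list1_reversed", "list2_same", "list2_diff",
                "pretrain_c", "pretrain_d", "blocked")},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExperimentStimuli":
        raw = json.loads(text)

        def dec_list(name: str) -> ProblemList:
            problems = []
            for entry in raw[name]:
                pair = tuple(
                    OdorPattern(label=o["label"], code=tuple(o["code"]))
                    for o in entry["pair"]
                )
                problems.append(
                    DiscriminationProblem(
                        odor_pair=pair,
                        rewarded=entry["rewarded"],
                        context=entry["context"],
                        index=entry["index"],
                    )
                )
            return ProblemList(list_id=name, problems=problems)

        return cls(**{name: dec_list(name) for name in raw})


def make_odor(rng: np.random.Generator, label: str = "odor") -> OdorPattern:
    """Draw a uniformly random exactly-6-hot code over the C(24,6) support."""
    on = rng.choice(GRID_CELLS, size=ACTIVE_CELLS, replace=False)
    code = np.zeros(GRID_CELLS, dtype=int)
    code[on] = 1
    return OdorPattern(label=label, code=tuple(int(c) for c in code))


def make_experiment_stimuli(
    rng: np.random.Generator,
    n_problems: int = 8,
    n_blocked: int = 10,
) -> ExperimentStimuli:
    """Generate every list for one simulated rat.

    All odors are drawn independently; baited sides are random with equal
    probability and fixed per problem across blocks.
    """
    x = [make_odor(rng, f"X{i + 1}") for i in range(max(n_problems, n_blocked))]
    y = [make_odor(rng, f"Y{i + 1}") for i in range(max(n_problems, n_blocked))]
    z = [make_odor(rng, f"Z{i + 1}") for i in range(n_problems)]
    w = [make_odor(rng, f"W{i + 1}") for i in range(n_problems)]

    list1_rewarded = rng.integers(0, 2, size=n_problems)
    list1 = ProblemList(
        "list1",
        [
            DiscriminationProblem((x[i], y[i]), int(list1_rewarded[i]), "A", i)
            for i in range(n_problems)
        ],
    )
    # Same pairs, opposite baited side, learned in context B.
    list1_rev = ProblemList(
        "list1_reversed",
        [
            DiscriminationProblem((x[i], y[i]), 1 - int(list1_rewarded[i]), "B", i)
            for i in range(n_problems)
        ],
    )
    # List 2: retain one odor per pair at random, pair it with novel W_i and
    # reverse the retained odor's reward status.
    retained_side = rng.integers(0, 2, size=n_problems)
    list2_problems = []
    for i in range(n_problems):
        retained = list1[i].odor_pair[int(retained_side[i])]
        was_rewarded = retained.label == list1[i].rewarded_odor.label
        pair = (retained, w[i])
        rewarded = 1 if was_rewarded else 0  # reversal: novel odor baited iff retained was
        list2_problems.append(DiscriminationProblem(pair, rewarded, "A", i))
    list2_same = ProblemList("list2_same", list2_problems)
    list2_diff = ProblemList(
        "list2_diff",
        [
            DiscriminationProblem(p.odor_pair, p.rewarded, "B", p.index)
            for p in list2_problems
        ],
    )

    pre_c_rewarded = rng.integers(0, 2, size=n_problems)
    pretrain_c = ProblemList(
        "pretrain_c",
        [
            DiscriminationProblem((x[i], z[i]), int(pre_c_rewarded[i]), "C", i)
            for i in range(n_problems)
        ],
    )
    pre_d_rewarded = rng.integers(0, 2, size=n_problems)
    pretrain_d = ProblemList(
        "pretrain_d",
        [
            DiscriminationProblem((z[i], y[i]), int(pre_d_rewarded[i]), "D", i)
            for i in range(n_problems)
        ],
    )

    blocked_rewarded = rng.integers(0, 2, size=n_blocked)
    blocked = ProblemList(
        "blocked",
        [
            DiscriminationProblem((x[i], y[i]), int(blocked_rewarded[i]), "A", i)
            for i in range(n_blocked)
        ],
    )
    return ExperimentStimuli(
        list1=list1,
        list1_reversed=list1_rev,
        list2_same=list2_same,
        list2_diff=list2_diff,
        pretrain_c=pretrain_c,
        pretrain_d=pretrain_d,
        blocked=blocked,
    )


def block_order(rng: np.random.Generator, problem_list: ProblemList) -> list[DiscriminationProblem]:
    """A fresh random permutation of the list for one block of trials."""
    order = rng.permutation(len(problem_list))
    return [problem_list[int(i)] for i in order]
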