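"""Oddball trial sequences and the eight-block experiment layout.

A block presents one syllable (lexical *fu* or nonlexical *lu*) under one
tonal contrast (T1/T6 or T4/T6), one tone as the rare deviant and the other
as the frequent standard.  Under study defaults a block has 535 trials, 80
of them deviants, stimulus onsets every 1200 ms (400 ms syllable + 800 ms
silence), and every run of standards between consecutive deviants has
length 5..11.  The full experiment crosses syllable type x contrast x
deviant role into eight blocks, presented in one of four rotations.

Sequence randomization draws uniformly from the set of label vectors
satisfying all constraints (including a minimum leading run of two
standards, needed so every deviant owns the two preceding standards the
trial-sorting scheme requires).  Uniformity is exact: a dynamic-programming
table counts the admissible (leading run, inter-deviant gaps, tail)
compositions and the sampler draws each part proportionally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

__all__ = [
    "DesignParams",
    "TrialSequence",
    "ExperimentPlan",
    "BLOCK_CONDITIONS",
    "generate_block",
    "is_feasible",
    "validate_sequence",
    "build_experiment",
    "write_sequence_tsv",
    "read_sequence_tsv",
]

#: Study defaults: trials per block, deviants per block, inter-deviant
#: standard-run bounds, onset-to-onset interval, syllable duration.
N_TRIALS = 535
N_DEVIANTS = 80
MIN_GAP = 5
MAX_GAP = 11
SOA_MS = 1200.0
SYLLABLE_MS = 400.0
ISI_MS = 800.0
MIN_LEADING = 2  # standards before the first deviant


@dataclass(frozen=True)
class DesignParams:
    n_trials: int = N_TRIALS
    n_deviants: int = N_DEVIANTS
    min_gap: int = MIN_GAP
    max_gap: int = MAX_GAP
    soa_ms: float = SOA_MS
    min_leading: int = MIN_LEADING


@dataclass(frozen=True)
class TrialSequence:
    """Ordered trial labels for one block.

    ``labels`` holds ``'standard'``/``'deviant'`` flags, ``stimulus_ids``
    the syllable+tone identity per trial (e.g. ``fu6``), ``onsets_ms`` the
    stimulus onset times, and ``block_id`` a descriptor of the condition
    (syllable, contrast, which tone is deviant).
    """

    labels: tuple[str, ...]
    stimulus_ids: tuple[str, ...]
    onsets_ms: np.ndarray
    block_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "onsets_ms", np.asarray(self.onsets_ms, float))
        if not (len(self.labels) == len(self.stimulus_ids) == len(self.onsets_ms)):
            raise ValueError("labels, stimulus_ids and onsets_ms must align")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def deviant_mask(self) -> np.ndarray:
        return np.array([l == "deviant" for l in self.labels])

    @property
    def n_deviants(self) -> int:
        return int(self.deviant_mask.sum())


@dataclass(frozen=True)
class BlockCondition:
    syllable: str          # 'fu' (lexical) or 'lu' (nonlexical)
    contrast: tuple[str, str]  # e.g. ('T1', 'T6')
    deviant_tone: str

    @property
    def standard_tone(self) -> str:
        a, b = self.contrast
        return b if self.deviant_tone == a else a

    @property
    def lexical(self) -> bool:
        return self.syllable == "fu"

    @property
    def block_id(self) -> str:
        return (
            f"{self.syllable}:{self.contrast[0]}/{self.contrast[1]}"
            f":dev={self.deviant_tone}"
        )


def _block_conditions() -> list[BlockCondition]:
    conds = []
    for syllable in ("fu", "lu"):
        for contrast in (("T1", "T6"), ("T4", "T6")):
            for deviant in contrast[::-1]:  # T6-deviant block first
                conds.append(BlockCondition(syllable, contrast, deviant))
    return conds


BLOCK_CONDITIONS: tuple[BlockCondition, ...] = tuple(_block_conditions())


@dataclass(frozen=True)
class ExperimentPlan:
    blocks: tuple[TrialSequence, ...]
    rotation_id: int
    conditions: tuple[BlockCondition, ...] = field(default=())


def is_feasible(
    n_trials: int, n_deviants: int, min_gap: int, max_gap: int,
    min_leading: int = MIN_LEADING,
) -> bool:
    """True iff a label vector satisfying all sequence constraints exists.

    Standards must supply a leading run of at least ``min_leading`` plus
    ``n_deviants - 1`` inter-deviant runs of at least ``min_gap``; the tail
    after the last deviant is unconstrained, so ``max_gap`` never limits
    feasibility (surplus standards park in the tail).
    """
    if min(n_trials, n_deviants, min_gap, max_gap) < 0 or max_gap < min_gap:
        return False
    n_std = n_trials - n_deviants
    if n_std < 0:
        return False
    if n_deviants == 0:
        return True
    return n_std >= min_leading + min_gap * (n_deviants - 1)


@lru_cache(maxsize=32)
def _gap_count_table(
    n_gaps: int, total: int, min_gap: int, max_gap: int
) -> np.ndarray:
    """count[k, s] = #ways to pick gaps k..n_gaps-1 (each in [min,max]) plus
    an unconstrained tail summing to s.  Object dtype keeps exact integers."""
    count = np.zeros((n_gaps + 1, total + 1), dtype=object)
    count[n_gaps, :] = 1  # tail absorbs anything
    for k in range(n_gaps - 1, -1, -1):
        for s in range(total + 1):
            acc = 0
            for g in range(min_gap, min(max_gap, s) + 1):
                acc += count[k + 1, s - g]
            count[k, s] = acc
    return count


def generate_block(
    n_trials: int = N_TRIALS,
    n_deviants: int = N_DEVIANTS,
    min_gap: int = MIN_GAP,
    max_gap: int = MAX_GAP,
    seed: int = 0,
    *,
    block: BlockCondition | None = None,
    soa_ms: float = SOA_MS,
    min_leading: int = MIN_LEADING,
) -> TrialSequence:
    """Sample a trial sequence uniformly from the admissible set.

    Raises ``ValueError`` naming the violated count bound when the
    parameters admit no valid sequence.  Identical seeds reproduce
    identical sequences.
    """
    if not is_feasible(n_trials, n_deviants, min_gap, max_gap, min_leading):
        n_std = n_trials - n_deviants
        need = min_leading + min_gap * max(n_deviants - 1, 0)
        raise ValueError(
            f"infeasible design: {n_std} standards cannot supply a leading run "
            f">= {min_leading} plus {max(n_deviants - 1, 0)} inter-deviant runs "
            f">= {min_gap} (needs >= {need})"
        )
    rng = np.random.default_rng(seed)
    n_std = n_trials - n_deviants
    if n_deviants == 0:
        labels = ["standard"] * n_trials
    else:
        n_gaps = n_deviants - 1
        # leading run L >= min_leading, gaps in [min_gap, max_gap], tail >= 0
        budget = n_std - min_leading
        table = _gap_count_table(n_gaps, budget, min_gap, max_gap)
        # draw leading surplus l (L = min_leading + l) with weight table[0, budget-l]
        weights = np.array(
            [float(table[0, budget - l]) for l in range(budget + 1)]
        )
        lead_extra = rng.choice(budget + 1, p=weights / weights.sum())
        remaining = budget - lead_extra
        gaps = []
        for k in range(n_gaps):
            opts = range(min_gap, min(max_gap, remaining) + 1)
            w = np.array([float(table[k + 1, remaining - g]) for g in opts])
            g = int(rng.choice(list(opts), p=w / w.sum()))
            gaps.append(g)
            remaining -= g
        labels = ["standard"] * (min_leading + int(lead_extra)) + ["deviant"]
        for g in gaps:
            labels += ["standard"] * g + ["deviant"]
        labels += ["standard"] * remaining
    assert len(labels) == n_trials
    if block is None:
        stimulus_ids = tuple(
            "dev" if l == "deviant" else "std" for l in labels
        )
        block_id = "unlabeled"
    else:
        stimulus_ids = tuple(
            block.syllable
            + (block.deviant_tone if l == "deviant" else block.standard_tone)[1:]
            for l in labels
        )
        block_id = block.block_id
    onsets = np.arange(n_trials, dtype=float) * soa_ms
    return TrialSequence(
        labels=tuple(labels),
        stimulus_ids=stimulus_ids,
        onsets_ms=onsets,
        block_id=block_id,
    )


def validate_sequence(
    seq: TrialSequence, params: DesignParams = DesignParams()
) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    report: list[str] = []
    if len(seq) != params.n_trials:
        report.append(f"trial count {len(seq)} != expected {params.n_trials}")
    n_dev = seq.n_deviants
    if n_dev != params.n_deviants:
        report.append(f"deviant count {n_dev} != expected {params.n_deviants}")
    dev_idx = np.flatnonzero(seq.deviant_mask)
    if len(dev_idx):
        lead = int(dev_idx[0])
        if lead < params.min_leading:
            report.append(
                f"leading standard run {lead} < minimum {params.min_leading}"
            )
        gaps = np.diff(dev_idx) - 1
        for pos, g in zip(dev_idx[1:], gaps):
            if not (params.min_gap <= g <= params.max_gap):
                report.append(
                    f"standard run of {g} before deviant at trial {pos} outside "
                    f"[{params.min_gap}, {params.max_gap}]"
                )
    onsets = seq.onsets_ms
    if len(onsets) > 1:
        steps = np.diff(onsets)
        if not np.allclose(steps, params.soa_ms):
            report.append(
                f"onsets not an arithmetic sequence with step {params.soa_ms} ms"
            )
    return report


#: Four block-order rotations: contrast order x which deviant role leads.
_ROTATIONS = {
    1: {"contrast_order": (("T1", "T6"), ("T4", "T6")), "t6_first": True},
    2: {"contrast_order": (("T4", "T6"), ("T1", "T6")), "t6_first": True},
    3: {"contrast_order": (("T1", "T6"), ("T4", "T6")), "t6_first": False},
    4: {"contrast_order": (("T4", "T6"), ("T1", "T6")), "t6_first": False},
}


def build_experiment(
    rotation_id: int,
    seed: int,
    params: DesignParams = DesignParams(),
) -> ExperimentPlan:
    """Assemble the 8-block plan for one participant rotation.

    For each tonal contrast, lexical (*fu*) blocks precede nonlexical
    (*lu*) blocks; consecutive blocks of the same syllable/contrast swap
    the deviant and standard tones.  The rotation selects which contrast
    comes first and which deviant role leads.
    """
    if rotation_id not in _ROTATIONS:
        raise ValueError(f"unknown rotation_id {rotation_id!r}; expected 1..4")
    rot = _ROTATIONS[rotation_id]
    order: list[BlockCondition] = []
    for contrast in rot["contrast_order"]:
        for syllable in ("fu", "lu"):
            roles = [c for c in BLOCK_CONDITIONS
                     if c.syllable == syllable and c.contrast == contrast]
            roles.sort(key=lambda c: c.deviant_tone != "T6")
            if not rot["t6_first"]:
                roles = roles[::-1]
            order.extend(roles)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(order)) % (2**31)
    blocks = tuple(
        generate_block(
            params.n_trials, params.n_deviants, params.min_gap, params.max_gap,
            int(s), block=cond, soa_ms=params.soa_ms,
            min_leading=params.min_leading,
        )
        for cond, s in zip(order, child_seeds)
    )
    return ExperimentPlan(blocks=blocks, rotation_id=rotation_id,
                          conditions=tuple(order))


def write_sequence_tsv(seq: TrialSequence, path: str | Path) -> None:
    lines = ["trial\tlabel\tstimulus_id\tonset_ms"]
    for i, (lab, sid, t) in enumerate(
        zip(seq.labels, seq.stimulus_ids, seq.onsets_ms)
    ):
        lines.append(f"{i}\t{lab}\t{sid}\t{t:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sequence_tsv(path: str | Path, block_id: str = "unlabeled") -> TrialSequence:
    labels, sids, onsets = [], [], []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        _, lab, sid, t = line.split("\t")
        labels.append(lab)
        sids.append(sid)
        onsets.append(float(t))
    return TrialSequence(tuple(labels), tuple(sids), np.array(onsets), block_id)


def sequence_to_json(seq: TrialSequence) -> str:
    return json.dumps(
        {
            "block_id": seq.block_id,
            "labels": list(seq.labels),
            "stimulus_ids": list(seq.stimulus_ids),
            "onsets_ms": [float(t) for t in seq.onsets_ms],
        }
    )
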