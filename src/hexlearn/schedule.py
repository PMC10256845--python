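"""Task designs for the hostile-expectation (HEX) shooting task and the
hostile-interpretation bias task (HIBT), plus outcome sampling.

The HEX task pits the participant against two opponents whose gun
probabilities are complementary (when opponent A draws a gun with
probability 0.8, opponent B does so with probability 0.2) and flip at
fixed block boundaries. A threat manipulation (points at stake or not)
runs in regular alternating blocks, orthogonal to the gun-probability
schedule. The default design is 160 trials in probability blocks of
40, 15, 25, 25, 15 and 40 trials with a 20-trial threat period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidDesignError

EMOTIONS = ("anger", "disgust", "fear", "joy")
INTENSITIES = (20, 40, 60, 80, 100)

DEFAULT_BLOCK_LENGTHS = (40, 15, 25, 25, 15, 40)
DEFAULT_P_HIGH = 0.8
DEFAULT_THREAT_PERIOD = 20


@dataclass(frozen=True)
class TaskSchedule:
    """Trial-by-trial HEX design.

    Attributes
    ----------
    block_lengths : tuple of int
        Lengths of the gun-probability blocks (sum = ``n_trials``).
    p_high : float
        The high gun probability; the low probability is ``1 - p_high``.
    p_gun_a : ndarray
        Opponent A's gun probability on each trial.
    opponent : ndarray of str
        Which opponent ('A' or 'B') is shown on each trial.
    threat : ndarray of str
        Threat condition ('high' or 'low') per trial.
    block_index : ndarray of int
        Zero-based probability-block index per trial.
    """

    block_lengths: tuple
    p_high: float
    p_gun_a: np.ndarray = field(repr=False)
    opponent: np.ndarray = field(repr=False)
    threat: np.ndarray = field(repr=False)
    block_index: np.ndarray = field(repr=False)

    @property
    def n_trials(self) -> int:
        return int(sum(self.block_lengths))

    @property
    def p_gun(self) -> np.ndarray:
        """Gun probability of the opponent actually shown on each trial."""
        return np.where(self.opponent == "A", self.p_gun_a, 1.0 - self.p_gun_a)

    @property
    def switch_trials(self) -> np.ndarray:
        """1-based trial numbers on which a probability block starts (after the first)."""
        return np.cumsum(self.block_lengths)[:-1] + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "opponent": self.opponent,
                "p_gun": self.p_gun,
                "threat": self.threat,
                "block": self.block_index,
            }
        )


@dataclass(frozen=True)
class OutcomeSequence:
    """Realized gun(1)/phone(0) outcomes for one run through a schedule."""

    u: np.ndarray
    seed: int
    mode: str

    def __len__(self) -> int:
        return len(self.u)


@dataclass(frozen=True)
class HibtDesign:
    """HIBT trial list: emotion x intensity cells, neutral and practice trials."""

    trials: pd.DataFrame  # columns: emotion, intensity (NaN for neutral), is_practice

    @property
    def main_trials(self) -> pd.DataFrame:
        return self.trials[~self.trials["is_practice"]]

    @property
    def n_main(self) -> int:
        return int((~self.trials["is_practice"]).sum())


def build_schedule(
    block_lengths=DEFAULT_BLOCK_LENGTHS,
    p_high: float = DEFAULT_P_HIGH,
    threat_period: int = DEFAULT_THREAT_PERIOD,
    threat_phase: str = "high",
    flip_start: bool = False,
    seed: int = 0,
) -> TaskSchedule:
    """Construct the HEX task design.

    Opponent A's gun probability starts at ``p_high`` (or ``1 - p_high``
    when ``flip_start``) and flips at every block boundary; opponent B's is
    complementary throughout. Threat alternates every ``threat_period``
    trials starting with ``threat_phase``. Opponents are interleaved
    pseudo-randomly with balanced counts inside every contiguous
    (probability block x threat block) segment, which keeps the shown-opponent
    gun-probability level statistically orthogonal to threat.
    """
    block_lengths = tuple(int(b) for b in block_lengths)
    if len(block_lengths) == 0 or any(b <= 0 for b in block_lengths):
        raise InvalidDesignError(f"block lengths must be positive, got {block_lengths}")
    if not 0.5 < p_high < 1.0:
        raise InvalidDesignError(f"p_high must lie in (0.5, 1), got {p_high}")
    n_trials = sum(block_lengths)
    if threat_period <= 0 or n_trials % threat_period != 0:
        raise InvalidDesignError(
            f"threat_period={threat_period} must divide n_trials={n_trials}"
        )
    if threat_phase not in ("high", "low"):
        raise InvalidDesignError(f"threat_phase must be 'high' or 'low', got {threat_phase!r}")

    p_levels = []
    p = 1.0 - p_high if flip_start else p_high
    for _ in block_lengths:
        p_levels.append(p)
        p = 1.0 - p
    p_gun_a = np.repeat(p_levels, block_lengths)
    block_index = np.repeat(np.arange(len(block_lengths)), block_lengths)

    phases = ("high", "low") if threat_phase == "high" else ("low", "high")
    threat = np.array(
        [phases[(t // threat_period) % 2] for t in range(n_trials)], dtype=object
    )

    # balanced opponent assignment within each (block, threat-run) segment
    rng = np.random.default_rng(seed)
    opponent = np.empty(n_trials, dtype=object)
    seg_id = np.cumsum(
        np.r_[True, (block_index[1:] != block_index[:-1]) | (threat[1:] != threat[:-1])]
    )
    for seg in np.unique(seg_id):
        idx = np.where(seg_id == seg)[0]
        n = len(idx)
        half = n // 2
        labels = np.array(["A"] * half + ["B"] * (n - half), dtype=object)
        if n % 2:  # odd segment: the extra slot goes to a random opponent
            labels[-1] = rng.choice(["A", "B"])
        rng.shuffle(labels)
        opponent[idx] = labels

    return TaskSchedule(
        block_lengths=block_lengths,
        p_high=float(p_high),
        p_gun_a=np.asarray(p_gun_a, dtype=float),
        opponent=opponent,
        threat=threat.astype(str),
        block_index=block_index,
    )


def sample_outcomes(schedule: TaskSchedule, seed: int, mode: str = "bernoulli") -> OutcomeSequence:
    """Draw a gun/phone outcome sequence from a schedule.

    ``bernoulli`` draws each trial independently at the shown opponent's
    gun probability. ``exact_proportion`` fixes, within every
    (probability block x opponent) group, the gun count to the nearest
    integer of p x group size, and permutes positions.
    """
    p = schedule.p_gun
    rng = np.random.default_rng(seed)
    if mode == "bernoulli":
        u = (rng.random(schedule.n_trials) < p).astype(int)
    elif mode == "exact_proportion":
        u = np.zeros(schedule.n_trials, dtype=int)
        for b in np.unique(schedule.block_index):
            for opp in ("A", "B"):
                idx = np.where((schedule.block_index == b) & (schedule.opponent == opp))[0]
                if len(idx) == 0:
                    continue
                n_gun = int(round(p[idx[0]] * len(idx)))
                guns = np.r_[np.ones(n_gun, dtype=int), np.zeros(len(idx) - n_gun, dtype=int)]
                rng.shuffle(guns)
                u[idx] = guns
    else:
        raise InvalidDesignError(f"unknown sampling mode {mode!r}")
    return OutcomeSequence(u=u, seed=int(seed), mode=mode)


def build_hibt_design(
    repetitions: int = 8, n_neutral: int = 8, n_practice: int = 16, seed: int = 0
) -> HibtDesign:
    """Build the HIBT trial list: 4 emotions x 5 intensities x ``repetitions``
    main trials plus ``n_neutral`` neutral trials, shuffled, with
    ``n_practice`` practice trials flagged separately up front."""
    if min(repetitions, n_neutral, n_practice) < 0:
        raise InvalidDesignError("counts must be non-negative")
    rng = np.random.default_rng(seed)

    rows = [
        (emo, float(inten), False)
        for emo in EMOTIONS
        for inten in INTENSITIES
        for _ in range(repetitions)
    ]
    rows += [("neutral", np.nan, False)] * n_neutral
    main = pd.DataFrame(rows, columns=["emotion", "intensity", "is_practice"])
    main = main.iloc[rng.permutation(len(main))].reset_index(drop=True)

    cells = [(e, float(i)) for e in EMOTIONS for i in INTENSITIES]
    picks = rng.choice(len(cells), size=n_practice, replace=True)
    practice = pd.DataFrame(
        [(cells[k][0], cells[k][1], True) for k in picks],
        columns=["emotion", "intensity", "is_practice"],
    )
    trials = (pd.concat([practice, main], ignore_index=True)
              if len(practice) else main)
    trials.insert(0, "trial", np.arange(1, len(trials) + 1))
    return HibtDesign(trials=trials)


def threat_probability_phi(schedule: TaskSchedule) -> float:
    """Phi (Matthews) association between threat level and the shown
    opponent's gun-probability level; ~0 means orthogonal factors."""
    a = (schedule.threat == "high").astype(int)
    b = (schedule.p_gun > 0.5).astype(int)
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    denom = np.sqrt(
        float(n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    )
    if denom == 0:
        return 0.0
    return (n11 * n00 - n10 * n01) / denom
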