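"""Probabilistic trial-sequence design for the interception task.

Each experimental block holds 45 trials: 30 "normal" balls (elasticity
0.65) and 15 "bouncy" balls (elasticity 0.85).  The probability of a normal
ball changes every 6, 9 or 12 trials ("game levels", p_normal in
{0.83, 0.67, 0.50}), and every block ends with a 9-trial catch level that
never carries explicit cues.  Control and cued blocks built from the same
sequence id share the exact same ball ordering; they differ only in the cue
annotations (hawkeye + bounceometer) attached to cued, non-catch levels.

Per-level ball counts are fixed quotas -- round((1 - p_normal) * length),
adjusted by at most +-1 so the block totals are exactly 30/15 -- rather
than i.i.d. draws, emulating the fixed pre-generated sequences used in the
task.  The catch level's underlying p_normal is set to 0.67 (a documented
convention; only its cue-free presentation is prescribed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "P_NORMAL_CHOICES",
    "LEVEL_LENGTHS",
    "CATCH_LENGTH",
    "CATCH_P_NORMAL",
    "DesignError",
    "LevelSpec",
    "CueInfo",
    "TrialPlan",
    "BlockPlan",
    "cue_for_level",
    "generate_block",
    "make_baseline_block",
    "validate_design",
    "max_constant_probability_run",
]

P_NORMAL_CHOICES = (0.83, 0.67, 0.50)
LEVEL_LENGTHS = (6, 9, 12)
CATCH_LENGTH = 9
CATCH_P_NORMAL = 0.67
BLOCK_TRIALS = 45
BLOCK_NORMAL = 30
BLOCK_BOUNCY = 15
BASELINE_TRIALS = 30

ELASTICITY_NORMAL = 0.65
ELASTICITY_BOUNCY = 0.85

#: bouncy-likelihood percent -> verbal label shown on the bounceometer
CUE_LABELS = {17: "low", 33: "medium", 50: "high"}
HAWKEYE_DURATION_S = 10.0
BOUNCEOMETER_LEAD_S = 3.0

#: internal seeds behind the three canonical trial-order sequences
_CANONICAL_SEQUENCE_SEEDS = {1: 160451, 2: 271828, 3: 314159}


class DesignError(ValueError):
    """Raised when no level composition can satisfy the ball quotas."""


@dataclass(frozen=True)
class CueInfo:
    bouncy_pct: int
    label: str
    hawkeye_duration_s: float = HAWKEYE_DURATION_S
    bounceometer_lead_s: float = BOUNCEOMETER_LEAD_S


@dataclass(frozen=True)
class LevelSpec:
    level_id: int
    length: int
    p_normal: float
    is_catch: bool = False


@dataclass(frozen=True)
class TrialPlan:
    trial_index: int
    ball_type: str  # "normal" | "bouncy"
    elasticity: float
    level_id: int
    p_normal: float
    cued: bool
    cue: Optional[CueInfo] = None


@dataclass(frozen=True)
class BlockPlan:
    block_kind: str  # "baseline" | "control" | "cued"
    trials: tuple[TrialPlan, ...]
    levels: tuple[LevelSpec, ...]
    sequence_id: int
    seed: int

    @property
    def ball_types(self) -> tuple[str, ...]:
        return tuple(t.ball_type for t in self.trials)

    def __len__(self) -> int:
        return len(self.trials)


def cue_for_level(p_normal: float) -> CueInfo:
    """Map a level's normal-ball probability to its explicit cue.

    0.83 -> 17% "low", 0.67 -> 33% "medium", 0.50 -> 50% "high".
    """
    if p_normal not in P_NORMAL_CHOICES:
        raise DesignError(f"p_normal must be one of {P_NORMAL_CHOICES}, got {p_normal}")
    pct = round(100 * (1.0 - p_normal))
    return CueInfo(bouncy_pct=pct, label=CUE_LABELS[pct])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _level_compositions() -> list[tuple[int, ...]]:
    """All ordered length sequences of 5 cued levels summing to 36 trials."""
    out = []

    def rec(prefix, remaining, slots):
        if slots == 0:
            if remaining == 0:
                out.append(tuple(prefix))
            return
        for length in LEVEL_LENGTHS:
            if length <= remaining - 6 * (slots - 1) and remaining - length >= 0:
                rec(prefix + [length], remaining - length, slots - 1)

    rec([], BLOCK_TRIALS - CATCH_LENGTH, 5)
    return out


_COMPOSITIONS = _level_compositions()


def _sample_probabilities(rng: np.random.Generator, n_levels: int) -> list[float]:
    """Probability per level; consecutive levels always differ and the final
    (catch) level is pinned at CATCH_P_NORMAL."""
    probs: list[float] = []
    for i in range(n_levels):
        if i == n_levels - 1:
            if probs and probs[-1] == CATCH_P_NORMAL:
                # re-signal change into the catch level by amending the
                # previous draw -- handled by caller via rejection
                return []
            probs.append(CATCH_P_NORMAL)
            continue
        options = [p for p in P_NORMAL_CHOICES if not probs or p != probs[-1]]
        probs.append(options[rng.integers(len(options))])
    return probs


def _solve_quotas(lengths: list[int], probs: list[float],
                  rng: np.random.Generator) -> Optional[list[int]]:
    """Bouncy count per level: round((1-p)*len) with +-1 adjustments so the
    block total is exactly BLOCK_BOUNCY.  Returns None when the composition
    cannot absorb the required adjustment."""
    base = [_round_half_up((1.0 - p) * n) for p, n in zip(probs, lengths)]
    deficit = BLOCK_BOUNCY - sum(base)
    if deficit == 0:
        return base
    step = 1 if deficit > 0 else -1
    order = list(rng.permutation(len(base)))
    quotas = list(base)
    for _ in range(abs(deficit)):
        adjusted = False
        for i in order:
            if quotas[i] != base[i]:
                continue  # at most +-1 per level
            cand = quotas[i] + step
            if 0 <= cand <= lengths[i]:
                quotas[i] = cand
                adjusted = True
                break
        if not adjusted:
            return None
    return quotas


def generate_block(seed: int, sequence_id: int, block_kind: str = "control",
                   max_attempts: int = 200) -> BlockPlan:
    """Generate a 45-trial experimental block.

    The trial sequence (level structure and ball ordering) is a
    deterministic function of ``(seed, sequence_id)`` alone, so control and
    cued blocks built from the same pair carry identical ball orderings.
    ``block_kind`` controls only the cue annotations.
    """
    if sequence_id not in (1, 2, 3):
        raise DesignError("sequence_id must be in {1, 2, 3}")
    if block_kind not in ("control", "cued"):
        raise DesignError("block_kind must be 'control' or 'cued'")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), _CANONICAL_SEQUENCE_SEEDS[sequence_id]])
    )
    for _ in range(max_attempts):
        lengths = list(_COMPOSITIONS[rng.integers(len(_COMPOSITIONS))]) + [CATCH_LENGTH]
        probs = _sample_probabilities(rng, len(lengths))
        if not probs:
            continue
        quotas = _solve_quotas(lengths, probs, rng)
        if quotas is None:
            continue
        return _assemble_block(seed, sequence_id, block_kind, lengths, probs,
                               quotas, rng)
    raise DesignError(
        "no level composition satisfied the 30/15 ball quota within "
        f"{max_attempts} attempts (quota constraint unsatisfiable)"
    )


def _assemble_block(seed, sequence_id, block_kind, lengths, probs, quotas,
                    rng) -> BlockPlan:
    levels = tuple(
        LevelSpec(level_id=i, length=n, p_normal=p, is_catch=(i == len(lengths) - 1))
        for i, (n, p) in enumerate(zip(lengths, probs))
    )
    trials: list[TrialPlan] = []
    idx = 0
    for level, n_bouncy in zip(levels, quotas):
        kinds = np.array(["bouncy"] * n_bouncy + ["normal"] * (level.length - n_bouncy))
        rng.shuffle(kinds)
        cued_level = block_kind == "cued" and not level.is_catch
        cue = cue_for_level(level.p_normal) if cued_level else None
        for k in kinds:
            trials.append(
                TrialPlan(
                    trial_index=idx,
                    ball_type=str(k),
                    elasticity=ELASTICITY_BOUNCY if k == "bouncy" else ELASTICITY_NORMAL,
                    level_id=level.level_id,
                    p_normal=level.p_normal,
                    cued=cued_level,
                    cue=cue,
                )
            )
            idx += 1
    return BlockPlan(
        block_kind=block_kind,
        trials=tuple(trials),
        levels=levels,
        sequence_id=sequence_id,
        seed=int(seed),
    )


def make_baseline_block() -> BlockPlan:
    """Thirty uncued trials, all normal balls at tennis-ball elasticity."""
    level = LevelSpec(level_id=0, length=BASELINE_TRIALS, p_normal=1.0, is_catch=False)
    trials = tuple(
        TrialPlan(
            trial_index=i,
            ball_type="normal",
            elasticity=ELASTICITY_NORMAL,
            level_id=0,
            p_normal=1.0,
            cued=False,
            cue=None,
        )
        for i in range(BASELINE_TRIALS)
    )
    return BlockPlan(block_kind="baseline", trials=trials, levels=(level,),
                     sequence_id=0, seed=0)


def max_constant_probability_run(block: BlockPlan) -> int:
    """Longest run of consecutive trials sharing one p_normal value."""
    best = run = 0
    prev = None
    for t in block.trials:
        run = run + 1 if t.p_normal == prev else 1
        prev = t.p_normal
        best = max(best, run)
    return best


def validate_design(block: BlockPlan) -> list[str]:
    """Check every block/level invariant; returns human-readable violations
    (empty iff the block is valid).  The validator reports, never raises."""
    v: list[str] = []
    if block.block_kind == "baseline":
        if len(block.trials) != BASELINE_TRIALS:
            v.append(f"baseline has {len(block.trials)} trials, expected {BASELINE_TRIALS}")
        for t in block.trials:
            if t.ball_type != "normal":
                v.append(f"trial {t.trial_index}: baseline ball_type != normal")
            if t.cued or t.cue is not None:
                v.append(f"trial {t.trial_index}: baseline trial flagged cued")
        return v

    if len(block.trials) != BLOCK_TRIALS:
        v.append(f"block has {len(block.trials)} trials, expected {BLOCK_TRIALS}")
    n_bouncy = sum(t.ball_type == "bouncy" for t in block.trials)
    if n_bouncy != BLOCK_BOUNCY:
        v.append(f"block has {n_bouncy} bouncy trials, expected {BLOCK_BOUNCY} (quota)")
    for lv in block.levels:
        if lv.is_catch:
            if lv.length != CATCH_LENGTH:
                v.append(f"level {lv.level_id}: catch length {lv.length} != {CATCH_LENGTH}")
            if lv.level_id != len(block.levels) - 1:
                v.append(f"level {lv.level_id}: catch level is not last")
        elif lv.length not in LEVEL_LENGTHS:
            v.append(f"level {lv.level_id}: length {lv.length} not in {set(LEVEL_LENGTHS)}")
        if lv.p_normal not in P_NORMAL_CHOICES:
            v.append(f"level {lv.level_id}: p_normal {lv.p_normal} not in {set(P_NORMAL_CHOICES)}")
    for a, b in zip(block.levels, block.levels[1:]):
        if a.p_normal == b.p_normal:
            v.append(f"levels {a.level_id},{b.level_id}: p_normal did not change")
    catch_ids = {lv.level_id for lv in block.levels if lv.is_catch}
    for t in block.trials[-CATCH_LENGTH:]:
        if t.level_id not in catch_ids:
            v.append(f"trial {t.trial_index}: final-nine trial outside catch level")
    for t in block.trials:
        if (t.ball_type == "normal") != (t.elasticity == ELASTICITY_NORMAL):
            v.append(f"trial {t.trial_index}: ball_type/elasticity mismatch")
        in_catch = t.level_id in catch_ids
        should_cue = block.block_kind == "cued" and not in_catch
        if t.cued != should_cue or (t.cue is not None) != should_cue:
            v.append(f"trial {t.trial_index}: cue presence violates block kind/catch rule")
    return v
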