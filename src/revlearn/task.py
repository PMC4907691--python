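"""Pavlovian aversive reversal-learning task design.

A session consists of four continuous blocks of twenty trials with two
visual cues (``A`` and ``B``). Within each block one cue is the CS+
(paired with a mild electric shock, the US, on a third of its
presentations: 4 reinforced out of 12) and the other is the CS- (never
reinforced, 8 presentations). Contingencies reverse between blocks, so
the cue roles alternate. Reversal instructions occupy a 10-s epoch after
trials 20, 40, and 60; in the uninstructed condition the same epoch is a
fixation period, so both groups share one timeline.

Sequences are pseudorandom under the design constraints:

* exactly ``reinforced_per_block`` US trials per block, only on CS+;
* no two US trials on adjacent trials (including across block bounds);
* the same cue never appears more than twice in a row;
* after each instruction, each cue is presented at least twice without
  reinforcement before the first US of the new block.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TrialSequence",
    "ReversalWindow",
    "ValidationReport",
    "ConstraintCheck",
    "SequenceGenerationError",
    "generate_trial_sequence",
    "validate_sequence",
    "instruction_windows",
    "canonical_orders",
]

CUES = ("A", "B")
CS_PLUS = "CS+"
CS_MINUS = "CS-"

EVENT_COLUMNS = ["trial", "onset_s", "cue", "role", "original_role", "us", "block"]
INSTRUCTION_COLUMNS = ["after_trial", "onset_s", "new_cs_plus"]


class SequenceGenerationError(RuntimeError):
    """Raised when no sequence satisfying the constraints is found."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the reversal-learning session."""

    n_blocks: int = 4
    trials_per_block: int = 20
    cs_plus_per_block: int = 12
    cs_minus_per_block: int = 8
    reinforced_per_block: int = 4
    stim_duration: float = 4.0
    isi: float = 12.0
    instruction_duration: float = 10.0
    min_unreinforced_after_instruction: int = 2
    max_run_same_cue: int = 2
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.cs_plus_per_block + self.cs_minus_per_block != self.trials_per_block:
            raise ValueError("cs_plus_per_block + cs_minus_per_block must equal trials_per_block")
        if not 0 <= self.reinforced_per_block <= self.cs_plus_per_block:
            raise ValueError("reinforced_per_block must lie in [0, cs_plus_per_block]")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_blocks and trials_per_block must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def reinforcement_rate(self) -> float:
        return self.reinforced_per_block / self.cs_plus_per_block

    @property
    def instruction_after_trials(self) -> tuple[int, ...]:
        """Trial indices (1-based) after which reversal instructions occur."""
        return tuple(self.trials_per_block * b for b in range(1, self.n_blocks))

    def cs_plus_cue(self, block: int) -> str:
        """Cue serving as CS+ in ``block`` (1-based); roles alternate."""
        return CUES[(block - 1) % 2]


@dataclass
class TrialSequence:
    """Ordered task events plus instruction events.

    ``events`` columns: trial (1-based), onset_s, cue, role (current
    contingencies), original_role (block-1 contingencies), us (0/1),
    block. ``instructions`` columns: after_trial, onset_s, new_cs_plus.
    """

    events: pd.DataFrame
    instructions: pd.DataFrame
    config: TaskConfig = field(default_factory=TaskConfig)

    @property
    def n_trials(self) -> int:
        return len(self.events)

    def to_tsv(self) -> tuple[str, str]:
        """Serialize (events, instructions) as TSV strings."""
        buf_e, buf_i = io.StringIO(), io.StringIO()
        self.events.to_csv(buf_e, sep="\t", index=False)
        self.instructions.to_csv(buf_i, sep="\t", index=False)
        return buf_e.getvalue(), buf_i.getvalue()

    @classmethod
    def from_tsv(cls, events_tsv: str, instructions_tsv: str,
                 config: TaskConfig | None = None) -> "TrialSequence":
        events = pd.read_csv(io.StringIO(events_tsv), sep="\t")
        instructions = pd.read_csv(io.StringIO(instructions_tsv), sep="\t")
        if instructions.empty:
            instructions = pd.DataFrame(columns=INSTRUCTION_COLUMNS)
        return cls(events=events[EVENT_COLUMNS], instructions=instructions,
                   config=config or TaskConfig())


@dataclass
class ReversalWindow:
    """Trials surrounding one instructed reversal.

    ``post_trials`` maps each cue to the unreinforced trials between the
    instruction and the first US of the new block; ``pre_trials`` maps
    each cue to the equally many unreinforced trials of that cue
    immediately preceding the instruction.
    """

    reversal_index: int
    after_trial: int
    new_cs_plus: str
    post_trials: dict[str, list[int]]
    pre_trials: dict[str, list[int]]

    def __post_init__(self) -> None:
        for cue in self.post_trials:
            if len(self.pre_trials[cue]) != len(self.post_trials[cue]):
                raise ValueError(f"pre/post trial counts differ for cue {cue}")

    @property
    def all_post(self) -> list[int]:
        return sorted(t for ts in self.post_trials.values() for t in ts)

    @property
    def all_pre(self) -> list[int]:
        return sorted(t for ts in self.pre_trials.values() for t in ts)


@dataclass
class ConstraintCheck:
    name: str
    passed: bool
    first_violation: int | None = None
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[ConstraintCheck]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed(self) -> list[ConstraintCheck]:
        return [c for c in self.checks if not c.passed]

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else f"FAIL@trial {c.first_violation} {c.detail}"
            lines.append(f"{c.name}: {status}")
        return "\n".join(lines)


def _sample_block(rng: np.random.Generator, config: TaskConfig, block: int,
                  prev_cues: list[str], prev_us: int,
                  role_template: list[int]) -> tuple[list[str], list[int]] | str:
    """One rejection-sampling attempt for a block.

    Shuffles the within-block roles, checks the cue-run constraint, then
    places the US trials on eligible CS+ positions (non-adjacent, after
    the post-instruction minimum presentations of each cue). Returns
    (cues, us) on success or the name of the violated constraint.
    """
    rng.shuffle(role_template)
    is_plus = role_template

    plus_cue = config.cs_plus_cue(block)
    minus_cue = CUES[1] if plus_cue == CUES[0] else CUES[0]
    cues = [plus_cue if p else minus_cue for p in is_plus]

    # max run of the same cue, counting the tail of the previous block
    seq_cues = prev_cues[-config.max_run_same_cue:] + cues
    run = 1
    for i in range(1, len(seq_cues)):
        if seq_cues[i] == seq_cues[i - 1]:
            run += 1
            if run > config.max_run_same_cue:
                return "max_run_same_cue"
        else:
            run = 1

    n = config.trials_per_block
    us = [0] * n
    if config.reinforced_per_block:
        if block > 1:
            # first US only after each cue was presented >= min times
            m = config.min_unreinforced_after_instruction
            ca = cb = 0
            earliest = n
            for i, cue in enumerate(cues):
                ca += cue == CUES[0]
                cb += cue == CUES[1]
                if ca >= m and cb >= m:
                    earliest = i + 1
                    break
        else:
            earliest = 0
        eligible = np.array([i for i, p in enumerate(is_plus)
                             if p and i >= earliest and (i > 0 or not prev_us)])
        if eligible.size < config.reinforced_per_block:
            return "min_unreinforced_after_instruction"
        for _ in range(32):  # non-adjacent US placement on the eligible set
            pos = rng.choice(eligible, size=config.reinforced_per_block, replace=False)
            pos.sort()
            if config.reinforced_per_block == 1 or np.diff(pos).min() > 1:
                for i in pos:
                    us[i] = 1
                break
        else:
            return "no_adjacent_us"
    return cues, us


def generate_trial_sequence(config: TaskConfig | None = None, seed: int = 0) -> TrialSequence:
    """Generate a pseudorandom trial sequence satisfying the design constraints.

    Rejection sampling over within-block shuffles, block by block, with a
    bounded retry budget (``config.max_attempts`` per block). Deterministic
    given ``(config, seed)``.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    cues: list[str] = []
    us: list[int] = []
    role_template = [1] * config.cs_plus_per_block + [0] * config.cs_minus_per_block
    for block in range(1, config.n_blocks + 1):
        last_fail = ""
        for _ in range(config.max_attempts):
            out = _sample_block(rng, config, block, cues, us[-1] if us else 0,
                                role_template)
            if isinstance(out, tuple):
                cues += out[0]
                us += out[1]
                break
            last_fail = out
        else:
            raise SequenceGenerationError(
                f"block {block}: no valid arrangement within {config.max_attempts} "
                f"attempts (last violated constraint: {last_fail})"
            )

    instruction_after = set(config.instruction_after_trials)
    rows, instr_rows = [], []
    t = 0.0
    for k in range(config.n_trials):
        trial = k + 1
        block = k // config.trials_per_block + 1
        cue = cues[k]
        role = CS_PLUS if cue == config.cs_plus_cue(block) else CS_MINUS
        original_role = CS_PLUS if cue == config.cs_plus_cue(1) else CS_MINUS
        rows.append((trial, t, cue, role, original_role, us[k], block))
        t += config.stim_duration + config.isi
        if trial in instruction_after:
            instr_rows.append((trial, t, config.cs_plus_cue(block + 1)))
            t += config.instruction_duration

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    instructions = pd.DataFrame(instr_rows, columns=INSTRUCTION_COLUMNS)
    return TrialSequence(events=events, instructions=instructions, config=config)


def validate_sequence(seq: TrialSequence, config: TaskConfig | None = None) -> ValidationReport:
    """Check every design constraint; never raises."""
    config = config or seq.config
    ev = seq.events
    checks: list[ConstraintCheck] = []

    def add(name: str, passed: bool, first: int | None = None, detail: str = "") -> None:
        checks.append(ConstraintCheck(name, bool(passed), first, detail))

    add("n_trials", len(ev) == config.n_trials,
        detail=f"expected {config.n_trials}, got {len(ev)}")

    block_sizes = ev.groupby("block").size()
    bad = block_sizes[block_sizes != config.trials_per_block]
    add("trials_per_block", bad.empty, detail=str(dict(bad)))

    ok, first, detail = True, None, ""
    for block, grp in ev.groupby("block"):
        n_plus = int((grp["role"] == CS_PLUS).sum())
        n_us = int(grp["us"].sum())
        if n_plus != config.cs_plus_per_block or n_us != config.reinforced_per_block:
            ok, first = False, int(grp["trial"].iloc[0])
            detail = f"block {block}: {n_plus} CS+, {n_us} US"
            break
    add("per_block_role_and_us_counts", ok, first, detail)

    ok, first = True, None
    for block, grp in ev.groupby("block"):
        expected = config.cs_plus_cue(block)
        plus_cues = grp.loc[grp["role"] == CS_PLUS, "cue"].unique()
        if len(plus_cues) != 1 or plus_cues[0] != expected:
            ok, first = False, int(grp["trial"].iloc[0])
            break
    add("roles_alternate_between_blocks", ok, first)

    viol = ev[(ev["role"] == CS_MINUS) & (ev["us"] == 1)]
    add("no_us_on_cs_minus", viol.empty,
        int(viol["trial"].iloc[0]) if not viol.empty else None)

    us_arr = ev["us"].to_numpy()
    adj = np.flatnonzero(us_arr[1:] + us_arr[:-1] > 1)
    add("no_adjacent_us", adj.size == 0,
        int(ev["trial"].iloc[adj[0] + 1]) if adj.size else None)

    cue_arr = ev["cue"].to_numpy()
    run, bad_idx = 1, None
    for i in range(1, len(cue_arr)):
        run = run + 1 if cue_arr[i] == cue_arr[i - 1] else 1
        if run > config.max_run_same_cue:
            bad_idx = int(ev["trial"].iloc[i])
            break
    add("max_run_same_cue", bad_idx is None, bad_idx)

    ok, first, detail = True, None, ""
    for after_trial in seq.instructions["after_trial"] if not seq.instructions.empty else []:
        block = int(after_trial) // config.trials_per_block + 1
        grp = ev[ev["block"] == block]
        us_idx = np.flatnonzero(grp["us"].to_numpy())
        upto = grp.iloc[: us_idx[0]] if us_idx.size else grp
        for cue in CUES:
            if int((upto["cue"] == cue).sum()) < config.min_unreinforced_after_instruction:
                ok, first = False, int(after_trial) + 1
                detail = f"cue {cue} underrepresented before first US of block {block}"
                break
        if not ok:
            break
    add("min_unreinforced_after_instruction", ok, first, detail)

    return ValidationReport(checks)


def instruction_windows(seq: TrialSequence) -> list[ReversalWindow]:
    """Post-instruction, pre-reinforcement windows with matched pre-instruction trials.

    Post trials run from the instruction to the trial before the first US
    of the new block; pre trials are, per cue, the equally many
    unreinforced trials immediately preceding the instruction.
    """
    if seq.instructions.empty:
        raise ValueError("sequence has no instruction events")
    config = seq.config
    ev = seq.events
    windows = []
    for i, row in enumerate(seq.instructions.itertuples(index=False), start=1):
        after = int(row.after_trial)
        block = after // config.trials_per_block + 1
        grp = ev[ev["block"] == block]
        us_idx = np.flatnonzero(grp["us"].to_numpy())
        post = grp.iloc[: us_idx[0]] if us_idx.size else grp
        post_trials: dict[str, list[int]] = {}
        pre_trials: dict[str, list[int]] = {}
        before = ev[(ev["trial"] <= after) & (ev["us"] == 0)]
        for cue in CUES:
            p = post.loc[post["cue"] == cue, "trial"].astype(int).tolist()
            if len(p) < config.min_unreinforced_after_instruction:
                raise ValueError(
                    f"reversal {i}: first US of block {block} precedes "
                    f"{config.min_unreinforced_after_instruction} presentations of cue {cue}"
                )
            prev = before.loc[before["cue"] == cue, "trial"].astype(int).tolist()
            if len(prev) < len(p):
                raise ValueError(f"reversal {i}: not enough pre-instruction trials of cue {cue}")
            post_trials[cue] = p
            pre_trials[cue] = prev[-len(p):]
        windows.append(ReversalWindow(
            reversal_index=i, after_trial=after, new_cs_plus=str(row.new_cs_plus),
            post_trials=post_trials, pre_trials=pre_trials,
        ))
    return windows


def canonical_orders(config: TaskConfig | None = None) -> tuple[TrialSequence, TrialSequence]:
    """The two canonical pseudorandom trial orders (seeds 1 and 2)."""
    config = config or TaskConfig()
    return generate_trial_sequence(config, seed=1), generate_trial_sequence(config, seed=2)
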