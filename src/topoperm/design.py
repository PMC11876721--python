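"""Cued repetition-probability trial structure (S1–S2 pairs).

Builds the within-subject 2 (repetition) x 2 (expectation) design in which a
subcategory of the first stimulus (S1) cues the probability that the second
stimulus (S2) repeats it.  One S1 subcategory signals a high repetition
probability (default 75%), the other a low one (default 25%); a repetition
under the high cue or an alternation under the low cue is *expected*, the
remaining combinations are *unexpected*.

Condition cells are allocated with exact counts (the published totals per
category are 180/180/60/60 for expected repetitions, expected alternations,
unexpected repetitions and unexpected alternations out of 480 trials), then
the row order is shuffled with a seeded generator.  Per-trial Bernoulli
sampling is deliberately avoided so that every dataset reproduces the design
cell sizes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "CELL_LABELS",
    "build_category_trials",
    "build_full_design",
    "condition_of",
    "read_trial_table",
    "write_trial_table",
]

#: The four condition cells of the repetition x expectation design.
CELL_LABELS = ("Exp_Rep", "Exp_Alt", "Unexp_Rep", "Unexp_Alt")

#: Columns of a trial table, in storage order.
TRIAL_COLUMNS = (
    "trial_index",
    "block",
    "category",
    "cue_level",
    "cue_label",
    "s1_id",
    "s2_id",
    "is_repetition",
    "is_expected",
    "is_target",
    "size_reduced",
)

#: Default stimulus categories and their S1 subcategories.  The first
#: subcategory cues the high repetition probability.
DEFAULT_CUE_LABELS = {
    "words": ("animate", "inanimate"),
    "faces": ("female", "male"),
    "animals": ("fish", "bird"),
}


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the cued repetition-probability design.

    Parameters
    ----------
    categories
        Stimulus category labels; each is presented in its own block.
    trials_per_category
        Total trials per category block.
    cue_labels
        Mapping from category to its two S1 subcategory labels.  The first
        label signals ``p_rep_given_highcue``, the second
        ``p_rep_given_lowcue``.
    p_rep_given_highcue, p_rep_given_lowcue
        Conditional probability that S2 repeats S1 given the cue.
    target_fraction
        Fraction of trials (per category) followed by a categorisation
        probe; target trials are excluded from ERP averaging downstream.
    n_stimuli_per_subcategory
        Size of the stimulus pool per subcategory.
    seed
        Seed for row-order shuffling and stimulus identity assignment.
    """

    categories: tuple[str, ...] = ("words", "faces", "animals")
    trials_per_category: int = 480
    cue_labels: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_CUE_LABELS)
    )
    p_rep_given_highcue: float = 0.75
    p_rep_given_lowcue: float = 0.25
    target_fraction: float = 0.20
    n_stimuli_per_subcategory: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_rep_given_highcue", "p_rep_given_lowcue", "target_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability in [0, 1]")
        if self.trials_per_category < 1:
            raise ValueError("trials_per_category must be positive")
        if self.n_stimuli_per_subcategory < 2:
            raise ValueError("need at least 2 stimuli per subcategory")
        for cat in self.categories:
            labels = self.cue_labels.get(cat)
            if labels is None or len(labels) != 2 or labels[0] == labels[1]:
                raise ValueError(
                    f"category {cat!r} needs exactly two distinct cue labels"
                )
        # Exact-count allocation: every cell size must be an integer.
        for cell, count in self._cell_counts_float().items():
            if abs(count - round(count)) > 1e-9:
                raise ValueError(
                    f"cell {cell!r} would receive a non-integer trial count "
                    f"({count:g}); adjust trials_per_category or the cue "
                    "probabilities"
                )
        n_targets = self.target_fraction * self.trials_per_category
        if abs(n_targets - round(n_targets)) > 1e-9:
            raise ValueError(
                f"target_fraction x trials_per_category = {n_targets:g} "
                "is not an integer"
            )

    def _cell_counts_float(self) -> dict[str, float]:
        half = self.trials_per_category / 2.0  # cues are equiprobable
        return {
            "Exp_Rep": half * self.p_rep_given_highcue,
            "Unexp_Alt": half * (1.0 - self.p_rep_given_highcue),
            "Unexp_Rep": half * self.p_rep_given_lowcue,
            "Exp_Alt": half * (1.0 - self.p_rep_given_lowcue),
        }

    def cell_counts(self) -> dict[str, int]:
        """Exact per-cell trial counts for one category."""
        return {cell: round(n) for cell, n in self._cell_counts_float().items()}

    def with_seed(self, seed: int) -> "DesignSpec":
        return replace(self, seed=seed)


def condition_of(row) -> str:
    """Map a trial row (mapping or Series) to its condition cell label."""
    cue = row["cue_level"]
    rep = bool(row["is_repetition"])
    if cue == "high_rep":
        return "Exp_Rep" if rep else "Unexp_Alt"
    if cue == "low_rep":
        return "Unexp_Rep" if rep else "Exp_Alt"
    raise ValueError(f"unknown cue level {cue!r}")


def _assign_stimuli(
    rows: pd.DataFrame,
    category: str,
    spec: DesignSpec,
    rng: np.random.Generator,
    no_reuse_window: int = 4,
) -> None:
    """Fill in s1_id / s2_id for an already row-ordered table, in place.

    S1 is drawn uniformly from the cued subcategory pool, excluding
    identities used in the previous `no_reuse_window` trials.  On repetition
    rows S2 equals S1; on alternation rows S2 is a different identity from
    the same category.  The alternation-pairing rule is a simulation policy,
    not an empirical constraint.
    """
    high_label, low_label = spec.cue_labels[category]
    pools = {
        label: [f"{category}/{label}/{i:03d}" for i in range(spec.n_stimuli_per_subcategory)]
        for label in (high_label, low_label)
    }
    all_ids = pools[high_label] + pools[low_label]
    recent: list[str] = []
    s1_ids, s2_ids = [], []
    for _, row in rows.iterrows():
        pool = pools[row["cue_label"]]
        candidates = [s for s in pool if s not in recent]
        if not candidates:  # tiny pools: fall back to the full pool
            candidates = pool
        s1 = candidates[rng.integers(len(candidates))]
        if row["is_repetition"]:
            s2 = s1
        else:
            others = [s for s in all_ids if s != s1]
            s2 = others[rng.integers(len(others))]
        s1_ids.append(s1)
        s2_ids.append(s2)
        recent.append(s1)
        if len(recent) > no_reuse_window:
            recent.pop(0)
    rows["s1_id"] = s1_ids
    rows["s2_id"] = s2_ids


def build_category_trials(
    spec: DesignSpec, category: str, block: int = 0
) -> pd.DataFrame:
    """Build the seeded trial table for one homogeneous category block.

    Cell counts are exact (computed from the cue-conditional repetition
    probabilities, cues equiprobable), the row order is shuffled, and target
    status is allocated per cell by flooring the per-cell share and handing
    the remainder out in fixed cell order, so the category total matches
    ``target_fraction`` exactly.
    """
    if category not in spec.categories:
        raise ValueError(f"unknown category {category!r}")
    counts = spec.cell_counts()
    high_label, low_label = spec.cue_labels[category]

    frames = []
    for cell, n in counts.items():
        cue = "high_rep" if cell in ("Exp_Rep", "Unexp_Alt") else "low_rep"
        frames.append(
            pd.DataFrame(
                {
                    "category": category,
                    "cue_level": cue,
                    "cue_label": high_label if cue == "high_rep" else low_label,
                    "is_repetition": cell in ("Exp_Rep", "Unexp_Rep"),
                    "is_target": _target_flags(spec, cell, n),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["is_expected"] = (table["cue_level"] == "high_rep") == table["is_repetition"]

    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _stable_hash(category), block])
    )
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    _assign_stimuli(table, category, spec, rng)
    # Which of S1/S2 is rendered 18% smaller; recorded only, no effect here.
    table["size_reduced"] = np.where(rng.random(len(table)) < 0.5, "s1", "s2")
    table["block"] = block
    table["trial_index"] = np.arange(len(table))
    return table[list(TRIAL_COLUMNS)]


def _target_flags(spec: DesignSpec, cell: str, n: int) -> np.ndarray:
    """Exact per-cell target allocation; remainder spread in cell order."""
    exact = spec.target_fraction * n
    base = int(np.floor(exact + 1e-9))
    n_extra = round(spec.target_fraction * spec.trials_per_category) - sum(
        int(np.floor(spec.target_fraction * c + 1e-9))
        for c in spec.cell_counts().values()
    )
    cells = list(spec.cell_counts())
    take_extra = cells.index(cell) < n_extra
    k = base + (1 if take_extra else 0)
    flags = np.zeros(n, dtype=bool)
    flags[:k] = True
    return flags


def _stable_hash(text: str) -> int:
    """Deterministic 31-bit hash of a label (process-independent)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def build_full_design(
    spec: DesignSpec, block_order: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Concatenate per-category blocks into the full session table.

    ``block_order`` selects the counterbalancing rotation of category
    blocks; it defaults to the order of ``spec.categories``.  Trial indices are
    global across the session.
    """
    if len(spec.categories) < 1:
        raise ValueError("spec must define at least one category")
    order = tuple(block_order) if block_order is not None else spec.categories
    if sorted(order) != sorted(spec.categories):
        raise ValueError("block_order must be a permutation of spec.categories")
    tables = [
        build_category_trials(spec, cat, block=i) for i, cat in enumerate(order)
    ]
    full = pd.concat(tables, ignore_index=True)
    full["trial_index"] = np.arange(len(full))
    return full


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("is_repetition", "is_expected", "is_target"):
        table[col] = table[col].astype(bool)
    return table[list(TRIAL_COLUMNS)]
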