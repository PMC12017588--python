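"""Synthetic pseudoknot-free structures and planted-label families.

The generator emits valid nested dot-brackets by recursive construction —
helices capped by hairpin, bulge, internal or multibranch loops, with
flanking end runs — and grows "families" by applying small
validity-preserving edits to a base structure. Families play the role of
RNA subclasses: members share a topology and differ by a few one-position
changes, so planted class labels are recoverable by similarity clustering.

All randomness flows through :class:`numpy.random.Generator`
(PCG64), so a fixed seed reproduces a dataset bit-for-bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import annotate, pair_table
from .structure_io import DotBracket, StructureArray

__all__ = [
    "SynthConfig",
    "random_structure",
    "mutate_family",
    "planted_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Geometry of a synthetic planted-label dataset.

    Defaults are sized so that a full score-matrix + clustering run
    finishes in seconds: 5 families of 6 members, base lengths 60-140 nt,
    4 mutation operations per member, hairpin loops of at least 3
    unpaired nucleotides.
    """

    seed: int = 0
    n_families: int = 5
    members_per_family: int = 6
    base_length_range: tuple[int, int] = (60, 140)
    min_hairpin: int = 3
    branch_prob: float = 0.25
    mutation_ops: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.base_length_range
        if lo > hi or lo < 12:
            raise ValueError(f"bad base_length_range {self.base_length_range}")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError(f"branch_prob must be in [0,1], got {self.branch_prob}")
        for name in ("n_families", "members_per_family", "min_hairpin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mutation_ops < 0:
            raise ValueError("mutation_ops must be >= 0")


def _helix(budget: int, cfg: SynthConfig, rng: np.random.Generator, depth: int) -> str:
    """A balanced helix-plus-loop substring of roughly `budget` characters."""
    min_hp = cfg.min_hairpin
    # helix length: geometric >= 2, capped so the loop still fits
    h = 2 + int(rng.geometric(0.45)) - 1
    h = max(2, min(h, (budget - min_hp) // 2))
    if h < 1:
        h = 1
    rest = budget - 2 * h
    branch_cost = 4 + min_hp  # cheapest possible branch helix
    loop: str
    if rest >= 2 * branch_cost + 2 and depth < 6 and rng.random() < cfg.branch_prob:
        # multiloop with 2 or 3 branches separated by short unpaired runs
        nb = 3 if (rest >= 3 * branch_cost + 4 and rng.random() < 0.3) else 2
        gaps = [int(rng.integers(1, 4)) for _ in range(nb + 1)]
        per_branch = (rest - sum(gaps)) // nb
        parts = [("." * gaps[0])]
        for b in range(nb):
            parts.append(_helix(max(branch_cost, per_branch), cfg, rng, depth + 1))
            parts.append("." * gaps[b + 1])
        loop = "".join(parts)
    elif rest >= branch_cost + 2 and depth < 12:
        # continue the stem through an internal loop or bulge
        if rng.random() < 0.5:
            left = int(rng.integers(1, 4))
            right = int(rng.integers(1, 4))
        else:
            side = int(rng.integers(1, 4))
            left, right = (side, 0) if rng.random() < 0.5 else (0, side)
        inner = rest - left - right
        if inner < branch_cost:
            loop = "." * max(min_hp, rest)
        else:
            loop = "." * left + _helix(inner, cfg, rng, depth + 1) + "." * right
    else:
        loop = "." * max(min_hp, rest)
    return "(" * h + loop + ")" * h


def random_structure(
    config: SynthConfig, rng: np.random.Generator, name: str = "synth"
) -> DotBracket:
    """Generate one valid pseudoknot-free dot-bracket.

    The structure has flanking end runs, one or two exterior helices and a
    recursively generated interior; every hairpin loop has at least
    ``config.min_hairpin`` unpaired positions, so annotation never errors.
    """
    lo, hi = config.base_length_range
    target = int(rng.integers(lo, hi + 1))
    e5 = int(rng.integers(0, 5))
    e3 = int(rng.integers(0, 5))
    interior = target - e5 - e3
    min_helix = 4 + config.min_hairpin
    if interior >= 2 * min_helix + 6 and rng.random() < 0.25:
        gap = int(rng.integers(1, 5))
        half = (interior - gap) // 2
        body = (
            _helix(half, config, rng, 0)
            + "." * gap
            + _helix(interior - gap - half, config, rng, 0)
        )
    else:
        body = _helix(max(min_helix, interior), config, rng, 0)
    return DotBracket(name=name, brackets="." * e5 + body + "." * e3)


def _hairpin_runs_ok(brackets: str, min_hairpin: int) -> bool:
    """Every hairpin run in the annotation has at least min_hairpin positions."""
    arr = annotate(DotBracket(name="_check", brackets=brackets))
    run = 0
    for ch in arr.codes + "$":
        if ch == "H":
            run += 1
        else:
            if 0 < run < min_hairpin:
                return False
            run = 0
    return True


def _apply_edit(
    brackets: str, cfg: SynthConfig, rng: np.random.Generator
) -> str | None:
    """One validity-preserving edit, or None if the drawn edit is impossible."""
    dbn = DotBracket(name="_edit", brackets=brackets)
    partner = pair_table(dbn)
    pairs = [(i, j) for i, j in partner.items() if j > i]
    unpaired = [i for i, j in partner.items() if j == 0]
    kind = rng.choice(
        ["helix_extend", "helix_shrink", "loop_extend", "loop_shrink",
         "add_branch", "remove_branch"]
    )
    s = brackets
    if kind == "helix_extend" and pairs:
        i, j = pairs[int(rng.integers(len(pairs)))]
        return s[: i - 1] + "(" + s[i - 1 : j] + ")" + s[j:]
    if kind == "helix_shrink" and len(pairs) > 1:
        i, j = pairs[int(rng.integers(len(pairs)))]
        out = s[: i - 1] + s[i : j - 1] + s[j:]
        return out if out.strip(".") else None
    if kind == "loop_extend" and unpaired:
        p = unpaired[int(rng.integers(len(unpaired)))]
        return s[: p - 1] + "." + s[p - 1 :]
    if kind == "loop_shrink" and unpaired:
        p = unpaired[int(rng.integers(len(unpaired)))]
        out = s[: p - 1] + s[p:]
        if out and _hairpin_runs_ok(out, cfg.min_hairpin):
            return out
        return None
    if kind == "add_branch" and unpaired:
        p = unpaired[int(rng.integers(len(unpaired)))]
        insert = "(" + "." * cfg.min_hairpin + ")"
        return s[: p - 1] + insert + s[p - 1 :]
    if kind == "remove_branch":
        # hairpin helices with nothing inside and a short loop
        candidates = []
        for i, j in pairs:
            interior_positions = range(i + 1, j)
            if all(partner[t] == 0 for t in interior_positions) and (
                j - i - 1 <= cfg.min_hairpin + 2
            ):
                candidates.append((i, j))
        if candidates and len(pairs) > len(candidates):
            i, j = candidates[int(rng.integers(len(candidates)))]
            out = s[: i - 1] + s[j:]
            return out if out.strip(".") else None
    return None


def mutate_family(
    base: DotBracket,
    members: int,
    ops: int,
    rng: np.random.Generator,
    *,
    config: SynthConfig | None = None,
    name_prefix: str | None = None,
) -> list[DotBracket]:
    """Derive `members` structures from a base by `ops` random edits each.

    Edits extend or shrink helices by one pair, grow or shrink unpaired
    runs by one position (respecting the minimum hairpin size), or add and
    remove short branch helices. Impossible edits are resampled with
    bounded retries, so every member remains a valid dot-bracket.
    """
    cfg = config or SynthConfig()
    prefix = name_prefix or base.name
    out: list[DotBracket] = []
    for m in range(members):
        brackets = base.brackets
        for _ in range(ops):
            for _attempt in range(30):
                edited = _apply_edit(brackets, cfg, rng)
                if edited is not None:
                    brackets = edited
                    break
        out.append(DotBracket(name=f"{prefix}_m{m:02d}", brackets=brackets))
    return out


def planted_dataset(
    config: SynthConfig,
) -> tuple[list[StructureArray], list[int]]:
    """Annotated structure arrays with planted family labels.

    Generates ``n_families`` independent base structures, expands each to
    ``members_per_family`` mutated members, annotates everything, and
    returns (arrays, labels) with labels equal to the family index.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    arrays: list[StructureArray] = []
    labels: list[int] = []
    for f in range(config.n_families):
        base = random_structure(config, rng, name=f"f{f:02d}")
        members = mutate_family(
            base,
            config.members_per_family,
            config.mutation_ops,
            rng,
            config=config,
        )
        for member in members:
            arrays.append(annotate(member))
            labels.append(f)
    return arrays, labels
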