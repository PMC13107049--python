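"""Combinatorics of the trichromatic FP11 tag library.

A tag is a copy-number triple (c_C, c_G, c_R) giving the tandem-repeat
counts of the CFP2, mNG3Asp and sfCherry3Csp 11th-strand fragments fused
to a carrier protein.  Copy numbers are drawn from a small level set
(default {0, 1, 2, 4, 8}); complemented brightness scales sub-linearly
with copy number, so each triple is an intensity barcode for one cell
population.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TagSpec",
    "TagLibrary",
    "enumerate_tag_library",
    "binary_label_capacity",
    "subset_count",
    "format_scientific",
    "DEFAULT_LEVELS",
]

#: Copy-number levels used for the screening library.
DEFAULT_LEVELS: tuple[int, ...] = (0, 1, 2, 4, 8)

_TAG_ID_RE = re.compile(r"^C(\d+)G(\d+)R(\d+)$")
_TRIPLE_RE = re.compile(r"^\(?\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*\)?$")


class EmptyLibraryError(ValueError):
    """Raised when enumeration filters away every candidate tag."""


@dataclass(frozen=True, order=True)
class TagSpec:
    """One copy-number barcode: repeats of the cyan, green and red FP11."""

    c_C: int
    c_G: int
    c_R: int

    def __post_init__(self) -> None:
        for name in ("c_C", "c_G", "c_R"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def tag_id(self) -> str:
        return f"C{self.c_C}G{self.c_G}R{self.c_R}"

    @property
    def total(self) -> int:
        return self.c_C + self.c_G + self.c_R

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.c_C, self.c_G, self.c_R)

    @classmethod
    def parse(cls, text: str) -> "TagSpec":
        """Parse either the canonical ``C{c}G{g}R{r}`` id or a ``(c, g, r)`` triple."""
        text = text.strip()
        m = _TAG_ID_RE.match(text) or _TRIPLE_RE.match(text)
        if m is None:
            raise ValueError(f"unrecognized tag spec {text!r}")
        return cls(int(m.group(1)), int(m.group(2)), int(m.group(3)))


@dataclass
class TagLibrary:
    """An ordered, duplicate-free collection of :class:`TagSpec`."""

    levels: tuple[int, ...]
    max_total: int | None
    include_null: bool
    tags: list[TagSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.tag_id for t in self.tags]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tag_id in library")
        levelset = set(self.levels)
        for t in self.tags:
            if not {t.c_C, t.c_G, t.c_R} <= levelset:
                raise ValueError(f"tag {t.tag_id} uses a copy number outside {sorted(levelset)}")
            if self.max_total is not None and t.total > self.max_total:
                raise ValueError(f"tag {t.tag_id} exceeds max_total={self.max_total}")
        has_null = any(t.as_tuple() == (0, 0, 0) for t in self.tags)
        if has_null and not self.include_null:
            raise ValueError("null tag present but include_null is False")

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self) -> Iterator[TagSpec]:
        return iter(self.tags)

    def __getitem__(self, i: int) -> TagSpec:
        return self.tags[i]

    @property
    def tag_ids(self) -> list[str]:
        return [t.tag_id for t in self.tags]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["tag_id", "c_C", "c_G", "c_R"])
            for t in self.tags:
                w.writerow([t.tag_id, t.c_C, t.c_G, t.c_R])

    @classmethod
    def from_csv(cls, path: str | Path) -> "TagLibrary":
        tags: list[TagSpec] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                tag = TagSpec(int(row["c_C"]), int(row["c_G"]), int(row["c_R"]))
                if row.get("tag_id") and row["tag_id"] != tag.tag_id:
                    raise ValueError(f"tag_id {row['tag_id']!r} does not match triple {tag.as_tuple()}")
                tags.append(tag)
        levels = tuple(sorted({c for t in tags for c in t.as_tuple()}))
        include_null = any(t.as_tuple() == (0, 0, 0) for t in tags)
        return cls(levels=levels, max_total=None, include_null=include_null, tags=tags)


def enumerate_tag_library(
    levels: Iterable[int] = DEFAULT_LEVELS,
    max_total: int | None = 12,
    include_null: bool = False,
) -> TagLibrary:
    """Enumerate every copy-number triple over ``levels`` subject to the
    summed-repeat bound.

    Parameters
    ----------
    levels
        Allowed copy numbers per channel (each ≥ 0).
    max_total
        Maximum summed repeats across the three channels, or ``None`` for
        unbounded.  The screening library uses 12, which yields 96 tags
        over the default levels once the all-zero triple is removed.
    include_null
        Whether to keep the (0, 0, 0) unlabeled tag.

    Returns
    -------
    TagLibrary
        Tags in lexicographic (c_C, c_G, c_R) order.
    """
    lv = tuple(sorted(set(int(x) for x in levels)))
    if not lv:
        raise ValueError("levels must be non-empty")
    if any(x < 0 for x in lv):
        raise ValueError("levels must be nonnegative")
    tags = []
    for c, g, r in product(lv, repeat=3):
        if max_total is not None and c + g + r > max_total:
            continue
        if (c, g, r) == (0, 0, 0) and not include_null:
            continue
        tags.append(TagSpec(c, g, r))
    if not tags:
        raise EmptyLibraryError(
            f"no tags over levels {lv} with max_total={max_total}, include_null={include_null}"
        )
    return TagLibrary(levels=lv, max_total=max_total, include_null=include_null, tags=tags)


def binary_label_capacity(n_colors: int) -> int:
    """Number of on/off color combinations of ``n_colors`` fluorophores,
    excluding the all-off state: 2**n − 1."""
    if not isinstance(n_colors, int) or n_colors < 1:
        raise ValueError(f"n_colors must be a positive integer, got {n_colors!r}")
    return 2**n_colors - 1


def subset_count(n_populations: int, k: int) -> int:
    """Exact number of k-subsets of n populations (binomial coefficient)."""
    if n_populations < 0 or k < 0:
        raise ValueError("n and k must be nonnegative")
    if k > n_populations:
        raise ValueError(f"k={k} exceeds n={n_populations}")
    return math.comb(n_populations, k)


def format_scientific(value: int, sig_figs: int = 1) -> str:
    """Render an exact integer in scientific notation at ``sig_figs``
    significant figures, e.g. ``2e+20`` for C(96, 20) at one figure."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be ≥ 1")
    if value == 0:
        return "0e+00"
    s = f"{value:.{sig_figs - 1}e}"
    return s
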