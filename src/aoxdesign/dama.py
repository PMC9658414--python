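"""Electron- and hydrogen-donating-ability map (eH-DAMA) triage.

Free-radical scavenging proceeds mainly by single electron transfer (SET)
and formal hydrogen atom transfer (f-HAT); the cheapest predictors of the
two are the ionization energy (IE) and the minimum bond-dissociation energy
(BDE) over the H-donor sites.  Plotting species at (IE, min BDE) puts the
most promising scavengers — good electron donors *and* good H donors — at
the bottom-left, below reference antioxidants such as Trolox, ascorbic acid
and α-tocopherol.

The map itself carries no numeric ranking rule, so this module makes one
explicit: Pareto-dominance ordering (both coordinates lower is strictly
better), with ties inside a front broken by range-normalised Euclidean
distance to the candidate set's component-wise minimum.  The rule is
invariant under per-axis affine rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReactivityIndexes",
    "DamaSelection",
    "build_eh_dama",
    "pareto_front",
    "export_dama_plot",
    "load_indexes",
]

#: Highly exergonic SET against the target radical sits in the Marcus
#: inverted region and can be kinetically slow despite looking ideal on the
#: map; flag candidates whose SET ΔG° is below this (kcal/mol).
MARCUS_INVERTED_WARNING_DG = -40.0


@dataclass
class ReactivityIndexes:
    """Reactivity indexes for one species (molecule + protonation state)."""

    species: str
    state: str = "neutral"
    IE: float = float("nan")            # eV
    EA: float | None = None             # eV
    BDE: dict[str, float] = field(default_factory=dict)  # site -> kcal/mol
    molar_fraction: float | None = None
    set_dG0: float | None = None        # vs the target radical, kcal/mol

    @property
    def min_BDE(self) -> float:
        if not self.BDE:
            raise ValueError(f"{self.species}/{self.state} has no BDE entries")
        return min(self.BDE.values())

    @property
    def coords(self) -> tuple[float, float]:
        return (self.IE, self.min_BDE)


@dataclass
class DamaSelection:
    """Ranked candidates with the selected subset and reference positions."""

    ranking: list[ReactivityIndexes]
    selected: list[ReactivityIndexes]
    references: list[ReactivityIndexes]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, r in enumerate(self.ranking, start=1):
            rows.append({"rank": rank, "species": r.species, "state": r.state,
                         "IE_eV": r.IE, "min_BDE_kcal_mol": r.min_BDE,
                         "molar_fraction": r.molar_fraction,
                         "selected": r in self.selected})
        for r in self.references:
            rows.append({"rank": None, "species": r.species, "state": r.state,
                         "IE_eV": r.IE, "min_BDE_kcal_mol": r.min_BDE,
                         "molar_fraction": r.molar_fraction,
                         "selected": False})
        return pd.DataFrame(rows)


def pareto_front(points: np.ndarray) -> np.ndarray:
    """Boolean mask of non-dominated points (lower is better on both axes)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = (
            (points <= points[i]).all(axis=1) & (points < points[i]).any(axis=1)
        )
        dominated[i] = False
        if dominated.any():
            mask[i] = False
    return mask


def _rank_key(points: np.ndarray) -> list[tuple[int, float]]:
    """(front index, normalised distance to component-wise minimum) per point."""
    pts = points.copy()
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0
    norm = (pts - lo) / span
    dist = np.sqrt((norm ** 2).sum(axis=1))

    front = np.full(len(pts), -1)
    remaining = np.arange(len(pts))
    level = 0
    work = pts.copy()
    while len(remaining):
        mask = pareto_front(work)
        front[remaining[mask]] = level
        remaining = remaining[~mask]
        work = work[~mask]
        level += 1
    return [(int(f), float(d)) for f, d in zip(front, dist)]


def build_eh_dama(candidates: list[ReactivityIndexes],
                  references: list[ReactivityIndexes],
                  cap: int = 6) -> DamaSelection:
    """Rank candidates on the (IE, min BDE) map and select up to ``cap``.

    Per-protonation-state entries are ranked separately (their molar
    fractions are carried through for the report).  A warning is attached
    for any candidate whose SET against the target radical is so exergonic
    that it falls in the Marcus inverted region.
    """
    if not candidates:
        return DamaSelection(ranking=[], selected=[], references=list(references))
    for r in candidates:
        if not np.isfinite(r.IE):
            raise ValueError(f"{r.species}/{r.state} has no ionization energy")
        r.min_BDE  # validates at least one BDE
    pts = np.array([c.coords for c in candidates])
    keys = _rank_key(pts)
    order = sorted(range(len(candidates)), key=lambda i: keys[i])
    ranking = [candidates[i] for i in order]
    warnings = [
        f"{c.species}/{c.state}: SET ΔG° = {c.set_dG0:g} kcal/mol is in the "
        "Marcus inverted region; the map may overstate its SET rate"
        for c in candidates
        if c.set_dG0 is not None and c.set_dG0 < MARCUS_INVERTED_WARNING_DG
    ]
    return DamaSelection(ranking=ranking, selected=ranking[:cap],
                         references=list(references), warnings=warnings)


def load_indexes(path: str | Path) -> list[ReactivityIndexes]:
    """Read a species index CSV (species, state, IE, EA, BDE_<site>... columns)."""
    df = pd.read_csv(path)
    bde_cols = [c for c in df.columns if c.startswith("BDE_")]
    out = []
    for row in df.itertuples(index=False):
        bde = {c[4:]: float(getattr(row, c)) for c in bde_cols
               if pd.notna(getattr(row, c))}
        out.append(ReactivityIndexes(
            species=str(row.species), state=str(getattr(row, "state", "neutral")),
            IE=float(row.IE), EA=float(row.EA) if hasattr(row, "EA") else None,
            BDE=bde,
            set_dG0=float(row.set_dG0) if hasattr(row, "set_dG0")
            and pd.notna(getattr(row, "set_dG0")) else None,
        ))
    return out


def export_dama_plot(selection: DamaSelection, path: str | Path) -> None:
    """Render the map to an SVG with all points labelled.

    Each marker's SVG group id encodes ``species|state|IE|minBDE`` with full
    float precision, so the plotted coordinates can be recovered from the
    file exactly.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for kind, entries, color, marker in (
        ("candidate", selection.ranking, "tab:blue", "o"),
        ("reference", selection.references, "tab:red", "^"),
    ):
        for e in entries:
            x, y = e.coords
            gid = f"dama:{kind}:{e.species}|{e.state}|{x!r}|{y!r}"
            ax.scatter([x], [y], c=color, marker=marker, gid=gid)
            ax.annotate(f"{e.species} ({e.state})", (x, y), fontsize=7,
                        textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("Ionization energy, IE (eV)")
    ax.set_ylabel("Minimum BDE (kcal/mol)")
    ax.set_title("Electron- and H-donating-ability map")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def parse_dama_plot(path: str | Path) -> list[tuple[str, str, str, float, float]]:
    """Recover (kind, species, state, IE, min BDE) tuples from an exported SVG."""
    import re

    text = Path(path).read_text()
    out = []
    for m in re.finditer(r'id="dama:([^:]+):([^|]+)\|([^|]*)\|([^|]+)\|([^"]+)"', text):
        kind, species, state, x, y = m.groups()
        out.append((kind, species, state, float(x), float(y)))
    return out
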