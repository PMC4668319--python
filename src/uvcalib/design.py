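"""Multilevel multifactor calibration designs.

A calibration set for resolving F co-absorbing components is laid out as
an L-level, F-factor design with L**2 mixtures in which every component
visits every concentration level exactly L times and the mean-centered
coded level columns are mutually orthogonal.  Orthogonality decorrelates
the component concentrations so each analyte's spectral contribution can
be estimated without confounding.

The module ships the concrete 4-level, 3-factor design used for the
cefoperazone (CEF) / 7-aminocephalosporanic acid (7-ACA) /
5-mercapto-1-methyl-tetrazole (5-MER) assay — 16 training mixtures plus
9 independent test mixtures inside the training concentration span — and
a seeded generator for the same family of designs at other L and F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np

from .io import ConcentrationTable

__all__ = [
    "DesignTable",
    "CheckResult",
    "cef_training_design",
    "cef_test_design",
    "build_balanced_design",
    "validate_design",
    "COMPONENTS",
]

COMPONENTS = ["CEF", "7-ACA", "5-MER"]

# 16 training mixtures of the 4-level, 3-factor design (ug/mL).
_TRAIN = [
    (18, 0.13, 0.065),
    (18, 0.15, 0.07),
    (20, 0.15, 0.09),
    (20, 0.20, 0.07),
    (26, 0.15, 0.065),
    (20, 0.13, 0.085),
    (18, 0.18, 0.085),
    (24, 0.18, 0.07),
    (24, 0.15, 0.085),
    (20, 0.18, 0.065),
    (24, 0.13, 0.09),
    (18, 0.20, 0.09),
    (26, 0.20, 0.085),
    (26, 0.18, 0.09),
    (24, 0.20, 0.065),
    (26, 0.13, 0.07),
]

# 9 independent validation mixtures within the design span (ug/mL).
_TEST = [
    (25, 0.17, 0.09),
    (19, 0.14, 0.07),
    (22, 0.18, 0.075),
    (21, 0.14, 0.08),
    (23, 0.15, 0.065),
    (25, 0.20, 0.085),
    (19, 0.13, 0.08),
    (22, 0.16, 0.07),
    (21, 0.16, 0.08),
]


@dataclass
class DesignTable:
    """Concentration design: I mixtures of F components with coded levels.

    ``coded_levels[i, f]`` is the rank (0..L-1, ascending concentration)
    of mixture i's concentration of component f within that component's
    ``level_values``.  Test sets, which are not laid on a level lattice,
    carry ``coded_levels=None``.
    """

    components: list[str]
    concentrations: np.ndarray
    coded_levels: np.ndarray | None = None
    level_values: dict[str, np.ndarray] = field(default_factory=dict)
    row_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.ndim != 2:
            raise ValueError("concentrations must be 2-D")
        i, f = self.concentrations.shape
        if len(self.components) != f:
            raise ValueError("component names must match column count")
        if self.row_labels is None:
            self.row_labels = [f"mix{k + 1}" for k in range(i)]
        if self.coded_levels is not None:
            self.coded_levels = np.asarray(self.coded_levels, dtype=int)
            if self.coded_levels.shape != (i, f):
                raise ValueError("coded_levels shape mismatch")
            for j, name in enumerate(self.components):
                vals = np.asarray(self.level_values[name], dtype=float)
                if not np.allclose(vals[self.coded_levels[:, j]],
                                   self.concentrations[:, j]):
                    raise ValueError(
                        f"coded levels inconsistent with concentrations "
                        f"for component {name!r}"
                    )

    @property
    def n_mixtures(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_components(self) -> int:
        return self.concentrations.shape[1]

    def to_concentration_table(self) -> ConcentrationTable:
        return ConcentrationTable(
            samples=list(self.row_labels),
            components=list(self.components),
            values=self.concentrations.copy(),
        )


def _code_by_rank(conc: np.ndarray, components: Sequence[str]):
    levels = {}
    coded = np.zeros(conc.shape, dtype=int)
    for j, name in enumerate(components):
        vals = np.unique(conc[:, j])
        levels[name] = vals
        coded[:, j] = np.searchsorted(vals, conc[:, j])
    return coded, levels


def cef_training_design() -> DesignTable:
    """The 16-mixture training design for the CEF/7-ACA/5-MER system.

    Levels: CEF {18, 20, 24, 26}, 7-ACA {0.13, 0.15, 0.18, 0.2},
    5-MER {0.065, 0.07, 0.085, 0.09} ug/mL; each level occurs 4 times per
    component and the coded columns are mutually orthogonal.
    """
    conc = np.array(_TRAIN, dtype=float)
    coded, levels = _code_by_rank(conc, COMPONENTS)
    return DesignTable(
        components=list(COMPONENTS),
        concentrations=conc,
        coded_levels=coded,
        level_values=levels,
        row_labels=[f"train{k + 1}" for k in range(len(_TRAIN))],
    )


def cef_test_design() -> DesignTable:
    """The 9-mixture independent test set, inside the training span."""
    conc = np.array(_TEST, dtype=float)
    return DesignTable(
        components=list(COMPONENTS),
        concentrations=conc,
        row_labels=[f"test{k + 1}" for k in range(len(_TEST))],
    )


# ---------------------------------------------------------------------------
# Generator: cyclic / permuted-column balanced designs
# ---------------------------------------------------------------------------

def _eulerian_base_column(n_levels: int, rng: np.random.Generator) -> np.ndarray:
    """Random Eulerian circuit over the complete digraph (with loops) on
    L vertices, as a level sequence of length L**2.

    Reading consecutive (cyclic) entries of the sequence enumerates every
    ordered level pair exactly once, so the column and its shift-by-one
    form a full two-factor factorial: balanced and exactly orthogonal.
    """
    L = n_levels
    # Hierholzer with seeded edge order
    succ = {u: list(rng.permutation(L)) for u in range(L)}
    start = int(rng.integers(L))
    stack, circuit = [start], []
    while stack:
        u = stack[-1]
        if succ[u]:
            stack.append(int(succ[u].pop()))
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    assert len(circuit) == L * L + 1 and circuit[0] == circuit[-1]
    return np.asarray(circuit[:-1], dtype=int)


def _orthogonal(a: np.ndarray, b: np.ndarray, tol: float = 1e-10) -> bool:
    ac, bc = a - a.mean(), b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        return False
    return abs(float(ac @ bc) / denom) <= tol


def build_balanced_design(
    level_values: Mapping[str, Sequence[float]],
    n_factors: int | None = None,
    seed: int = 0,
    max_tries: int = 200,
) -> DesignTable:
    """Generate an L-level, F-factor design of L**2 mixtures.

    Every factor column is a permutation of one base multiset (each level
    exactly L times) and mean-centered coded columns are pairwise
    orthogonal to |r| <= 1e-10.  The base column is a seeded Eulerian
    level sequence; the second column is its cyclic shift (orthogonal by
    construction) and further columns are seeded searches over shifts and
    permutations.  Deterministic for a fixed seed.
    """
    names = list(level_values)
    if n_factors is None:
        n_factors = len(names)
    if n_factors != len(names):
        raise ValueError("n_factors must match the number of components")
    if n_factors < 2:
        raise ValueError("need at least 2 factors")
    counts = {name: len(level_values[name]) for name in names}
    L = counts[names[0]]
    if any(c != L for c in counts.values()):
        raise ValueError(f"all components must have the same level count, got {counts}")
    if L < 2:
        raise ValueError("need at least 2 levels")
    for name in names:
        vals = np.asarray(level_values[name], dtype=float)
        if len(np.unique(vals)) != L:
            raise ValueError(f"duplicate level values for component {name!r}")

    rng = np.random.default_rng(seed)
    n = L * L
    for _ in range(max_tries):
        base = _eulerian_base_column(L, rng)
        cols = [base, np.roll(base, -1)]
        ok = True
        for _f in range(2, n_factors):
            cand = _next_column(cols, base, rng)
            if cand is None:
                ok = False
                break
            cols.append(cand)
        if ok:
            break
    else:
        raise RuntimeError(
            f"no balanced orthogonal design found for L={L}, F={n_factors} "
            f"after {max_tries} attempts"
        )

    coded = np.column_stack(cols)
    conc = np.empty((n, n_factors), dtype=float)
    levels = {}
    for j, name in enumerate(names):
        vals = np.sort(np.asarray(level_values[name], dtype=float))
        levels[name] = vals
        conc[:, j] = vals[coded[:, j]]
    return DesignTable(
        components=names,
        concentrations=conc,
        coded_levels=coded,
        level_values=levels,
    )


def _next_column(cols, base, rng, n_shift_tries: int = 64,
                 n_perm_tries: int = 2000):
    """Find one more column orthogonal to all existing ones: try cyclic
    shifts of the base first, then seeded random permutations."""
    n = base.size
    for k in rng.permutation(np.arange(2, n)):
        cand = np.roll(base, -int(k))
        if all(_orthogonal(cand, c) for c in cols):
            return cand
    for _ in range(n_perm_tries):
        cand = rng.permutation(base)
        if all(_orthogonal(cand, c) for c in cols):
            return cand
    return None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class CheckResult:
    name: str
    passed: bool
    value: object
    detail: str = ""


def validate_design(
    design: DesignTable,
    reference_span: DesignTable | None = None,
    r_tol: float = 1e-10,
) -> list[CheckResult]:
    """Run named structural checks; failures are reported, never raised.

    Checks: per-component level balance (each level appears I/L times),
    pairwise orthogonality of mean-centered coded columns, and — when
    ``reference_span`` is given — that every concentration lies within
    the reference design's per-component min-max span.
    """
    checks: list[CheckResult] = []
    if design.coded_levels is None:
        coded, _ = _code_by_rank(design.concentrations, design.components)
    else:
        coded = design.coded_levels

    for j, name in enumerate(design.components):
        col = coded[:, j]
        levels, counts = np.unique(col, return_counts=True)
        if len(levels) < 2:
            checks.append(CheckResult(
                f"balance[{name}]", True, dict(zip(levels.tolist(), counts.tolist())),
                "single level: balance trivially holds",
            ))
            continue
        expected = design.n_mixtures / len(levels)
        balanced = np.all(counts == expected)
        checks.append(CheckResult(
            f"balance[{name}]", bool(balanced),
            dict(zip(levels.tolist(), counts.tolist())),
            f"expected {expected:g} occurrences per level",
        ))

    for a in range(design.n_components):
        for b in range(a + 1, design.n_components):
            na, nb = design.components[a], design.components[b]
            ca = coded[:, a] - coded[:, a].mean()
            cb = coded[:, b] - coded[:, b].mean()
            denom = np.linalg.norm(ca) * np.linalg.norm(cb)
            if denom == 0:
                checks.append(CheckResult(
                    f"orthogonality[{na},{nb}]", True, None,
                    "skipped: a column has a single level",
                ))
                continue
            r = float(ca @ cb) / denom
            checks.append(CheckResult(
                f"orthogonality[{na},{nb}]", abs(r) <= r_tol, r,
                f"|Pearson r| tolerance {r_tol:g}",
            ))

    if reference_span is not None:
        for j, name in enumerate(design.components):
            ref = reference_span.concentrations[:, reference_span.components.index(name)]
            col = design.concentrations[:, j]
            inside = bool(col.min() >= ref.min() and col.max() <= ref.max())
            checks.append(CheckResult(
                f"span[{name}]", inside,
                (float(col.min()), float(col.max())),
                f"reference span [{ref.min():g}, {ref.max():g}]",
            ))
    return checks
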