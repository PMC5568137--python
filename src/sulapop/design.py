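"""Small design-matrix builder shared by the mixed-model and CJS code.

Model formulas are given as lists of term strings rather than a string
DSL.  Supported elementary terms:

``"x"``        centered continuous covariate
``"x^2"``      square of the centered covariate
``"C(x)"``     factor with treatment (drop-first) coding
``"a:b"``      interaction: column-wise products of two elementary terms

An intercept column is always included first.  Centering constants and
factor levels are frozen at build time so the same design can be applied
to new data for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignInfo", "build_design", "apply_design"]


@dataclass
class DesignInfo:
    """Frozen metadata needed to rebuild a design on new data."""

    terms: list[str]
    centers: dict[str, float] = field(default_factory=dict)
    levels: dict[str, list] = field(default_factory=dict)
    column_names: list[str] = field(default_factory=list)


def _parse_part(part: str) -> tuple[str, str]:
    """Return (kind, variable) for one elementary term."""
    part = part.strip()
    if part.startswith("C(") and part.endswith(")"):
        return "factor", part[2:-1].strip()
    if part.endswith("^2"):
        return "quadratic", part[:-2].strip()
    return "linear", part


def _build_part(df: pd.DataFrame, part: str, info: DesignInfo, fitting: bool):
    kind, var = _parse_part(part)
    if var not in df.columns:
        raise KeyError(f"term {part!r}: column {var!r} not in data")
    col = df[var]
    if kind == "factor":
        if fitting:
            levels = sorted(pd.unique(col).tolist())
            info.levels[var] = levels
        else:
            levels = info.levels[var]
            unseen = set(col) - set(levels)
            if unseen:
                raise ValueError(f"factor {var!r}: unseen levels {sorted(unseen)}")
        # treatment coding, first level is the reference
        block = np.column_stack(
            [(col.to_numpy() == lev).astype(float) for lev in levels[1:]]
        ) if len(levels) > 1 else np.empty((len(col), 0))
        names = [f"C({var})[{lev}]" for lev in levels[1:]]
        return block, names
    x = col.to_numpy(dtype=float)
    if fitting:
        info.centers.setdefault(var, float(np.mean(x)))
    xc = x - info.centers[var]
    if kind == "quadratic":
        return xc[:, None] ** 2, [f"{var}^2"]
    return xc[:, None], [var]


def _build_term(df: pd.DataFrame, term: str, info: DesignInfo, fitting: bool):
    parts = term.split(":")
    if len(parts) == 1:
        return _build_part(df, parts[0], info, fitting)
    if len(parts) != 2:
        raise ValueError(f"only two-way interactions supported: {term!r}")
    a, anames = _build_part(df, parts[0], info, fitting)
    b, bnames = _build_part(df, parts[1], info, fitting)
    cols, names = [], []
    for i, na in enumerate(anames):
        for j, nb in enumerate(bnames):
            cols.append(a[:, i] * b[:, j])
            names.append(f"{na}:{nb}")
    block = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return block, names


def build_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, DesignInfo]:
    """Build a fixed-effects design matrix (with intercept) from term strings."""
    info = DesignInfo(terms=list(terms))
    blocks = [np.ones((len(df), 1))]
    names = ["Intercept"]
    for term in terms:
        block, bnames = _build_term(df, term, info, fitting=True)
        blocks.append(block)
        names.extend(bnames)
    X = np.hstack(blocks)
    info.column_names = names
    # drop aliased (exactly collinear) columns is the caller's concern; we
    # report rank so callers can raise a helpful error
    return X, info


def apply_design(df: pd.DataFrame, info: DesignInfo) -> np.ndarray:
    """Rebuild the design on new data using frozen centers and levels."""
    blocks = [np.ones((len(df), 1))]
    for term in info.terms:
        block, _ = _build_term(df, term, info, fitting=False)
        blocks.append(block)
    return np.hstack(blocks)
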