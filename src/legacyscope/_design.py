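"""Model-matrix construction from factor tables.

A small formula-free builder: terms are column names, ``a:b`` interactions or
``a*b`` expansions. Categorical columns are dummy-coded with the first sorted
level as reference; numeric columns enter as-is. The per-column term
assignment supports sequential (type-I) sums of squares downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["expand_terms", "model_matrix"]


def expand_terms(terms: list[str]) -> list[str]:
    """Expand ``a*b`` into ``a, b, a:b`` preserving order, dropping repeats."""
    out: list[str] = []
    for term in terms:
        if "*" in term:
            parts = [p.strip() for p in term.split("*")]
            for p in parts:
                if p not in out:
                    out.append(p)
            inter = ":".join(parts)
            if inter not in out:
                out.append(inter)
        elif term.strip() not in out:
            out.append(term.strip())
    return out


def _main_effect(design: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    if name not in design.columns:
        raise ValueError(f"unknown design column {name!r}")
    col = design[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(float)[:, None], [name]
    levels = sorted(pd.unique(col.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"term {name!r} has a single level")
    cols = [(col.astype(str) == lev).to_numpy(float) for lev in levels[1:]]
    names = [f"{name}[{lev}]" for lev in levels[1:]]
    return np.column_stack(cols), names


def model_matrix(
    design: pd.DataFrame, terms: list[str], intercept: bool = True
) -> tuple[np.ndarray, list[str], list[str]]:
    """Build (X, column_names, column_term_assignment) from ordered terms."""
    terms = expand_terms(terms)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    assign: list[str] = []
    if intercept:
        blocks.append(np.ones((len(design), 1)))
        names.append("Intercept")
        assign.append("Intercept")
    for term in terms:
        parts = term.split(":")
        mats, nms = zip(*(_main_effect(design, p) for p in parts))
        block = mats[0]
        labels = list(nms[0])
        for mat, nm in zip(mats[1:], nms[1:]):
            block = np.einsum("ij,ik->ijk", block, mat).reshape(len(design), -1)
            labels = [f"{a}:{b}" for a in labels for b in nm]
        blocks.append(block)
        names.extend(labels)
        assign.extend([term] * block.shape[1])
    X = np.column_stack(blocks) if blocks else np.empty((len(design), 0))
    return X, names, assign
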