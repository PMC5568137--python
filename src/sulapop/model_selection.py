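"""AICc model-set machinery shared by the mixed-model and CJS stages.

Candidate sets are all additive combinations of a global term list,
restricted by marginality: a quadratic requires its linear term and an
interaction requires both main effects.  Ranking follows the usual
information-theoretic conventions: ΔAICc relative to the top model,
Akaike weights, a "strong support" band at ΔAICc ≤ 2 and a reporting
cut at ΔAICc ≤ 7, and a flag for models that are more complex nested
versions of a better model (such models gain their support purely from
the ~2-unit penalty per extra parameter).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["aicc", "generate_model_set", "rank_models", "implied_hierarchy"]

#: strong-support and reporting cuts on the ΔAICc scale
STRONG_SUPPORT_DELTA = 2.0
REPORT_DELTA = 7.0


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike Information Criterion.

    ``aicc = -2*loglik + 2k + 2k(k+1)/(n-k-1)``; requires ``n > k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def implied_hierarchy(terms: list[str]) -> dict[str, set[str]]:
    """Derive marginality requirements from term syntax.

    ``x^2`` requires ``x``; ``a:b`` requires ``a`` and ``b`` (whenever the
    main effects appear in the global list).
    """
    tset = set(terms)
    hier: dict[str, set[str]] = {t: set() for t in terms}
    for t in terms:
        if ":" in t:
            for part in t.split(":"):
                if part in tset:
                    hier[t].add(part)
        elif t.endswith("^2"):
            base = t[:-2]
            if base in tset:
                hier[t].add(base)
    return hier


def _check_acyclic(hier: dict[str, set[str]]) -> None:
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        if state.get(node) == 1:
            raise ValueError(f"cyclic hierarchy declaration at term {node!r}")
        if state.get(node) == 2:
            return
        state[node] = 1
        for dep in hier.get(node, ()):
            visit(dep)
        state[node] = 2

    for t in hier:
        visit(t)


def generate_model_set(
    global_terms: list[str],
    hierarchy: dict[str, set[str]] | None = None,
) -> list[tuple[str, ...]]:
    """All term subsets of the global model satisfying marginality.

    Parameters
    ----------
    global_terms
        Terms of the most complex candidate model.
    hierarchy
        Mapping term -> set of terms it requires.  If omitted it is
        derived from the term syntax (quadratics and interactions).

    Returns
    -------
    list of tuples of terms, deduplicated, ordered by size then lexically.
    The empty tuple (intercept-only model) and the global model are always
    members.
    """
    terms = list(dict.fromkeys(global_terms))
    hier = hierarchy if hierarchy is not None else implied_hierarchy(terms)
    _check_acyclic(hier)
    models = []
    for r in range(len(terms) + 1):
        for subset in combinations(terms, r):
            s = set(subset)
            if all(hier.get(t, set()) <= s for t in subset):
                models.append(tuple(subset))
    # dedupe while keeping deterministic order
    seen: set[tuple[str, ...]] = set()
    out = []
    for m in sorted(models, key=lambda m: (len(m), m)):
        if m not in seen:
            seen.add(m)
            out.append(m)
    return out


def rank_models(
    fits: dict[str, object],
    delta_report: float = REPORT_DELTA,
    strong: float = STRONG_SUPPORT_DELTA,
) -> pd.DataFrame:
    """Rank fitted models by AICc.

    Parameters
    ----------
    fits
        Mapping model id -> fit object exposing ``loglik``, ``k``, ``n``
        and (optionally) ``terms`` (iterable of term strings, used for
        the nested-model flag).
    delta_report
        Models with ΔAICc above this cut are dropped from the table.
    strong
        ΔAICc cut for the strongly supported set.

    Returns
    -------
    DataFrame with columns ``model, k, loglik, aicc, delta_aicc, weight,
    strong_support, nested_flag``, sorted ascending by AICc (ties broken
    by smaller k then model id).  Akaike weights are computed over the
    full candidate set before truncation and sum to one there.
    """
    if not fits:
        raise ValueError("no fits supplied")
    ns = {getattr(f, "n") for f in fits.values()}
    if len(ns) != 1:
        raise ValueError(f"fits computed on differing n: {sorted(ns)}")
    rows = []
    for mid, f in fits.items():
        rows.append(
            {
                "model": mid,
                "k": int(getattr(f, "k")),
                "loglik": float(getattr(f, "loglik")),
                "aicc": float(getattr(f, "aicc")),
                "terms": frozenset(getattr(f, "terms", ()) or ()),
            }
        )
    tab = pd.DataFrame(rows).sort_values(
        ["aicc", "k", "model"], kind="mergesort"
    ).reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    rel = np.exp(-0.5 * tab["delta_aicc"].to_numpy())
    tab["weight"] = rel / rel.sum()
    tab["strong_support"] = tab["delta_aicc"] <= strong
    # nested flag: strict superset of a strictly better-ranked model's terms
    nested = []
    for i in range(len(tab)):
        ti = tab["terms"].iloc[i]
        flag = any(
            tab["terms"].iloc[j] < ti for j in range(i)
        )
        nested.append(flag)
    tab["nested_flag"] = nested
    tab = tab[tab["delta_aicc"] <= delta_report].drop(columns=["terms"])
    return tab.reset_index(drop=True)
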