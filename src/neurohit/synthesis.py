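"""Synthetic tabular augmentation by sequential conditional synthesis.

A 24-song feature table is far too small to train nonlinear classifiers, so
it is inflated to a large synthetic table the way the synthpop-style
procedure does: columns are visited in a fixed order; the first is drawn by
bootstrap from its marginal, and each later column is modelled by a
recursive-partitioning tree on the previously synthesized columns, with each
synthetic value sampled uniformly from the *source* values in the leaf the
synthetic row falls into (donor sampling).  Donor sampling guarantees every
synthetic value occurs in the source (donor closure) and preserves the joint
structure the trees can see.

``validate_synthesis`` operationalizes "statistically identical" as effect
size tolerances — per-column mean and SD shifts in source-SD units and
pairwise correlation shifts — rather than hypothesis tests, which at
n = 10,000 would reject trivially small differences.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = [
    "SynthesisConfig",
    "SyntheticTable",
    "SynthesisReport",
    "synthesize_table",
    "validate_synthesis",
    "split_half",
]


@dataclass
class SynthesisConfig:
    n_rows: int = 10_000
    visit_order: tuple[str, ...] = ("label", "avg_immersion", "retreat", "peak_immersion")
    # per-column override: "bootstrap" | "tree_donor" | "normal"
    method_per_column: dict | None = None
    min_leaf: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be at least 1")
        if len(set(self.visit_order)) != len(self.visit_order):
            raise ValueError("visit_order must list each column exactly once")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be at least 1")


@dataclass
class SyntheticTable:
    table: pd.DataFrame
    provenance: dict  # source digest, config echo, seed


@dataclass
class SynthesisReport:
    passed: bool
    column_stats: pd.DataFrame  # per-column mean/SD differences in source-SD units
    corr_stats: pd.DataFrame  # pairwise correlation differences
    failures: list


def _source_digest(source: pd.DataFrame) -> str:
    return hashlib.sha256(
        source.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def _is_categorical(col: pd.Series) -> bool:
    return col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)


def _encode(col: pd.Series, categories: dict) -> np.ndarray:
    """Numeric view of a column for use as a tree predictor."""
    name = col.name
    if name in categories:
        mapping = categories[name]
        return col.map(mapping).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def synthesize_table(source: pd.DataFrame, config: SynthesisConfig | None = None) -> SyntheticTable:
    """Inflate a small feature table into a seeded synthetic table.

    Only the columns in ``config.visit_order`` are synthesized; other source
    columns are ignored.  The source must have at least two rows and no
    missing values in the synthesized columns.
    """
    config = config if config is not None else SynthesisConfig()
    config.validate()
    missing_cols = [c for c in config.visit_order if c not in source.columns]
    if missing_cols:
        raise ValueError(f"source lacks columns {missing_cols}")
    src = source[list(config.visit_order)].reset_index(drop=True)
    if len(src) < 2:
        raise ValueError("source must have at least 2 rows")
    if src.isna().any().any():
        raise ValueError("source contains missing values")

    rng = np.random.default_rng(config.seed)
    n_src = len(src)
    methods = dict(config.method_per_column or {})
    categories = {
        c: {v: i for i, v in enumerate(pd.unique(src[c]))}
        for c in config.visit_order
        if _is_categorical(src[c])
    }

    synth = pd.DataFrame(index=range(config.n_rows))
    for j, col in enumerate(config.visit_order):
        default = "bootstrap" if j == 0 else "tree_donor"
        method = methods.get(col, default)
        # trees need at least one possible split
        if method == "tree_donor" and n_src < 2 * config.min_leaf:
            method = "bootstrap" if _is_categorical(src[col]) else "normal"
        if method == "bootstrap":
            donors = rng.integers(0, n_src, size=config.n_rows)
            synth[col] = src[col].to_numpy()[donors]
        elif method == "tree_donor":
            prev = list(config.visit_order[:j])
            X_src = np.column_stack([_encode(src[c], categories) for c in prev])
            X_syn = np.column_stack([_encode(synth[c], categories) for c in prev])
            y = src[col]
            if _is_categorical(y) or pd.unique(y).size == 1:
                tree = DecisionTreeClassifier(
                    min_samples_leaf=config.min_leaf, random_state=int(rng.integers(2**31))
                )
                tree.fit(X_src, y.astype(str))
            else:
                tree = DecisionTreeRegressor(
                    min_samples_leaf=config.min_leaf, random_state=int(rng.integers(2**31))
                )
                tree.fit(X_src, y.to_numpy(dtype=float))
            src_leaf = tree.apply(X_src)
            syn_leaf = tree.apply(X_syn)
            # uniform donor draw within each leaf
            values = np.empty(config.n_rows, dtype=object)
            for leaf in np.unique(syn_leaf):
                members = np.flatnonzero(src_leaf == leaf)
                picks = members[rng.integers(0, members.size, size=int((syn_leaf == leaf).sum()))]
                values[syn_leaf == leaf] = y.to_numpy()[picks]
            synth[col] = values if _is_categorical(y) else values.astype(float)
        elif method == "normal":
            # parametric fallback: linear-Gaussian conditional on earlier columns
            prev = list(config.visit_order[:j])
            y = src[col].to_numpy(dtype=float)
            if prev:
                X_src = np.column_stack(
                    [np.ones(n_src)] + [_encode(src[c], categories) for c in prev]
                )
                beta, *_ = np.linalg.lstsq(X_src, y, rcond=None)
                resid = y - X_src @ beta
                sd = float(np.std(resid, ddof=min(len(beta), n_src - 1)))
                X_syn = np.column_stack(
                    [np.ones(config.n_rows)]
                    + [_encode(synth[c], categories) for c in prev]
                )
                mean = X_syn @ beta
            else:
                mean = np.full(config.n_rows, y.mean())
                sd = float(np.std(y, ddof=1))
            synth[col] = mean + rng.normal(0.0, sd, config.n_rows)
        else:
            raise ValueError(f"unknown synthesis method {method!r} for column {col}")

    provenance = {
        "source_digest": _source_digest(src),
        "config": {**asdict(config), "visit_order": list(config.visit_order)},
        "seed": config.seed,
        "n_source_rows": n_src,
    }
    return SyntheticTable(table=synth, provenance=provenance)


def _numeric_view(df: pd.DataFrame, columns, categories: dict) -> pd.DataFrame:
    out = {}
    for c in columns:
        col = df[c]
        if c in categories:
            out[c] = col.map(categories[c]).astype(float)
        else:
            out[c] = col.astype(float)
    return pd.DataFrame(out)


def validate_synthesis(
    source: pd.DataFrame,
    synthetic: pd.DataFrame,
    tolerance_sd: float = 0.25,
    tolerance_corr: float = 0.15,
) -> SynthesisReport:
    """Check distributional fidelity of a synthetic table against its source.

    Passes iff for every column |mean shift|/source SD <= ``tolerance_sd``,
    |SD shift|/source SD <= ``tolerance_sd``, and every pairwise correlation
    moves by at most ``tolerance_corr``.  Categorical columns are compared on
    an integer encoding shared between the two tables.
    """
    cols = [c for c in synthetic.columns if c != "__weight__"]
    if set(cols) - set(source.columns):
        raise ValueError(
            f"column mismatch: synthetic has {sorted(set(cols) - set(source.columns))} "
            "not present in source"
        )
    categories = {
        c: {v: i for i, v in enumerate(pd.unique(source[c]))}
        for c in cols
        if _is_categorical(source[c])
    }
    src = _numeric_view(source, cols, categories)
    syn = _numeric_view(synthetic, cols, categories)

    failures = []
    rows = []
    for c in cols:
        sd = float(src[c].std(ddof=1))
        scale = sd if sd > 0 else 1.0
        d_mean = float(syn[c].mean() - src[c].mean()) / scale
        d_sd = float(syn[c].std(ddof=1) - sd) / scale
        ok = abs(d_mean) <= tolerance_sd and abs(d_sd) <= tolerance_sd
        if not ok:
            failures.append(f"column {c}: mean shift {d_mean:+.3f} SD, SD shift {d_sd:+.3f} SD")
        rows.append(
            {"column": c, "mean_shift_sd": d_mean, "sd_shift_sd": d_sd, "passed": ok}
        )
    corr_rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if src[a].std() == 0 or src[b].std() == 0 or syn[a].std() == 0 or syn[b].std() == 0:
                continue
            r_src = float(src[a].corr(src[b]))
            r_syn = float(syn[a].corr(syn[b]))
            ok = abs(r_syn - r_src) <= tolerance_corr
            if not ok:
                failures.append(
                    f"correlation ({a}, {b}): source {r_src:+.3f} vs synthetic {r_syn:+.3f}"
                )
            corr_rows.append(
                {"a": a, "b": b, "r_source": r_src, "r_synthetic": r_syn, "passed": ok}
            )
    return SynthesisReport(
        passed=not failures,
        column_stats=pd.DataFrame(rows),
        corr_stats=pd.DataFrame(corr_rows),
        failures=failures,
    )


def split_half(table: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint halves of an even-row table (train, test)."""
    n = len(table)
    if n % 2 != 0:
        raise ValueError(f"split_half requires an even row count, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    half = n // 2
    train = table.iloc[perm[:half]].reset_index(drop=True)
    test = table.iloc[perm[half:]].reset_index(drop=True)
    return train, test
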