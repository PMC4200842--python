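"""Descriptor-matrix assembly, PLS regression, LOO validation and model search.

The QSAR matrix X collects field values (one column per grid point per
field kind) over the molecule rows; y is the pIC50 vector.  Models are
single-response PLS fitted by NIPALS on column-centered data.  Internal
validity is judged by leave-one-out cross-validation,

    Q² = 1 − Σ(Y_pred − Y_exp)² / Σ(Y_exp − Y_mean)² ,

with Y_mean the full-training-set mean activity, and the usual companion
statistics: SEP = sqrt(PRESS/(n−c−1)), the non-cross-validated R²_ncv,
SEE = sqrt(RSS/(n−c−1)), the regression F-ratio, and the external R²_pred
on a held-out test set.  The number of latent components (OPN) is chosen by
maximum Q² (ties to the smaller count); an alternative minimum-SEE
criterion is available.  A field-combination search evaluates every
non-empty subset of the five CoMSIA fields — 31 candidate models — and
ranks them by Q².
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import Molecule
from .field_engine import COMFA_KINDS, COMSIA_KINDS, FieldBlock, Lattice

_SHORT_LABEL = {
    "CoMSIA_S": "S",
    "CoMSIA_E": "E",
    "CoMSIA_H": "H",
    "CoMSIA_D": "D",
    "CoMSIA_A": "A",
    "CoMFA_steric": "S",
    "CoMFA_electrostatic": "E",
}

_ZERO_SD_TOL = 1e-12


@dataclass
class DescriptorMatrix:
    """Filtered, mean-substituted descriptor matrix with scaling metadata.

    ``X_raw`` holds the kept columns on their original scale; scaling
    factors are recomputed from whatever row subset a fit uses (so LOO can
    re-derive them per fold) while the kept-column set stays frozen.
    """

    X_raw: np.ndarray
    y: np.ndarray
    column_labels: list[tuple[str, int]]  # (field_kind, grid point index)
    block_kinds: list[str]
    block_of_col: np.ndarray  # index into block_kinds per column
    dropped: dict[str, list[tuple[str, int]]]
    scaling: str
    split_labels: np.ndarray
    lattice: Lattice
    mol_ids: list[str]
    substituted: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return self.X_raw.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X_raw.shape[1]

    @property
    def train_rows(self) -> np.ndarray:
        return np.flatnonzero(self.split_labels != "test")

    @property
    def test_rows(self) -> np.ndarray:
        return np.flatnonzero(self.split_labels == "test")

    def scale_factors(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-column multiplicative factors for the requested row subset.

        ``block_standard`` weights each field block equally: every column of
        a block is divided by the square root of the block's total column
        variance, so each block contributes unit total variance.
        """
        if self.scaling == "none":
            return np.ones(self.n_columns)
        if self.scaling != "block_standard":
            raise ValueError(f"unknown scaling mode {self.scaling!r}")
        rows = self.train_rows if rows is None else rows
        factors = np.ones(self.n_columns)
        for b, _kind in enumerate(self.block_kinds):
            cols = np.flatnonzero(self.block_of_col == b)
            if cols.size == 0:
                continue
            total_var = float(self.X_raw[np.ix_(rows, cols)].var(axis=0, ddof=1).sum())
            if total_var > 0:
                factors[cols] = 1.0 / math.sqrt(total_var)
        return factors

    def columns_of_kind(self, field_kind: str) -> np.ndarray:
        return np.array(
            [i for i, (k, _) in enumerate(self.column_labels) if k == field_kind],
            dtype=int,
        )


def default_min_sigma(field_kind: str) -> float:
    """Column-filter threshold: 2.0 kcal/mol for CoMFA, 0 for CoMSIA."""
    return 2.0 if field_kind in COMFA_KINDS else 0.0


def assemble_matrix(
    blocks: list[FieldBlock],
    y: np.ndarray,
    min_sigma: float | dict[str, float] | None = None,
    scaling: str = "block_standard",
    split_labels: np.ndarray | list[str] | None = None,
) -> DescriptorMatrix:
    """Concatenate field blocks into a filtered QSAR descriptor matrix.

    Columns with training-row standard deviation below the per-kind
    ``min_sigma`` (and all constant columns) are dropped with a recorded
    reason.  Flagged entries of the CoMFA electrostatic block (steric cap
    region) are replaced by the training-set column mean of the unflagged
    entries before filtering.
    """
    if not blocks:
        raise ValueError("no field blocks supplied")
    y = np.asarray(y, dtype=float)
    n = blocks[0].values.shape[0]
    lattice = blocks[0].lattice
    ids = blocks[0].mol_ids
    for blk in blocks:
        if blk.values.shape[0] != n or blk.mol_ids != ids:
            raise ValueError("blocks disagree on molecules")
        if blk.lattice != lattice:
            raise ValueError("blocks disagree on the lattice")
    if y.shape != (n,):
        raise ValueError("activity vector length does not match block rows")
    if split_labels is None:
        split_labels = np.array(["train"] * n)
    split_labels = np.asarray(split_labels)
    train = np.flatnonzero(split_labels != "test")
    if train.size == 0:
        raise ValueError("no training rows")

    parts, labels, block_idx = [], [], []
    dropped: dict[str, list[tuple[str, int]]] = {"zero variance": [], "below min_sigma": []}
    substituted: list[tuple[str, int]] = []
    for b, blk in enumerate(blocks):
        vals = blk.values.astype(float).copy()
        if blk.flags is not None:
            vals = _mean_substitute(vals, blk.flags, train, blk.field_kind, substituted)
        if isinstance(min_sigma, dict):
            thresh = min_sigma.get(blk.field_kind, default_min_sigma(blk.field_kind))
        elif min_sigma is None:
            thresh = default_min_sigma(blk.field_kind)
        else:
            thresh = float(min_sigma)
        sd = vals[train].std(axis=0, ddof=1)
        keep = ~((sd <= _ZERO_SD_TOL) | (sd < thresh))
        for j in np.flatnonzero(~keep):
            reason = "zero variance" if sd[j] <= _ZERO_SD_TOL else "below min_sigma"
            dropped[reason].append((blk.field_kind, int(j)))
        parts.append(vals[:, keep])
        labels.extend((blk.field_kind, int(j)) for j in np.flatnonzero(keep))
        block_idx.extend([b] * int(keep.sum()))
    X = np.hstack(parts) if parts else np.empty((n, 0))
    if X.shape[1] == 0:
        raise ValueError("no descriptor columns survive filtering")
    return DescriptorMatrix(
        X_raw=X,
        y=y,
        column_labels=labels,
        block_kinds=[b.field_kind for b in blocks],
        block_of_col=np.array(block_idx, dtype=int),
        dropped=dropped,
        scaling=scaling,
        split_labels=split_labels,
        lattice=lattice,
        mol_ids=list(ids),
        substituted=substituted,
    )


def _mean_substitute(vals, flags, train, kind, record) -> np.ndarray:
    for j in range(vals.shape[1]):
        col_flags = flags[:, j]
        if not col_flags.any():
            continue
        ok = train[~col_flags[train]]
        fill = vals[ok, j].mean() if ok.size else 0.0
        vals[col_flags, j] = fill
        record.append((kind, j))
    return vals


# ---------------------------------------------------------------------------
# NIPALS PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted single-response PLS model on the original column scale."""

    n_components: int
    x_weights: np.ndarray   # (p, c), scaled-centered space
    x_loadings: np.ndarray  # (p, c)
    y_loadings: np.ndarray  # (c,)
    scores: np.ndarray      # (n_train, c)
    coef: np.ndarray        # (p,), original column scale
    intercept: float
    column_labels: list[tuple[str, int]]
    scale_factors: np.ndarray
    train_rows: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def field_kinds(self) -> list[str]:
        seen: list[str] = []
        for k, _ in self.column_labels:
            if k not in seen:
                seen.append(k)
        return seen

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        return np.asarray(X_raw, dtype=float) @ self.coef + self.intercept


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS latent-variable extraction for a single response.

    Deflates X after every component; raises when the requested component
    count exceeds the effective rank of the centered matrix.
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(
                f"n_components={n_components} exceeds the rank of the centered matrix"
            )
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise ValueError(
                f"n_components={n_components} exceeds the rank of the centered matrix"
            )
        p_vec = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_vec)
        y = y - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_vec, t, q_a
    return W, P, T, q


def pls_fit(
    M: DescriptorMatrix,
    n_components: int,
    rows: np.ndarray | None = None,
) -> PLSModel:
    """Fit NIPALS PLS on the training rows (or an explicit row subset).

    Column scaling factors are recomputed from the fitting rows; the
    regression coefficients are back-transformed so that
    ``y ≈ X_raw @ coef + intercept`` on the original column scale.
    """
    rows = M.train_rows if rows is None else np.asarray(rows)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    max_rank = min(rows.size - 1, M.n_columns)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound {max_rank}"
        )
    factors = M.scale_factors(rows)
    Xs = M.X_raw[rows] * factors
    x_mean = Xs.mean(axis=0)
    y_mean = float(M.y[rows].mean())
    W, P, T, q = _nipals(Xs - x_mean, M.y[rows] - y_mean, n_components)
    # b = W (P'W)^{-1} q, then undo the column scaling
    coef_scaled = W @ np.linalg.solve(P.T @ W, q)
    coef = coef_scaled * factors
    intercept = y_mean - float(M.X_raw[rows].mean(axis=0) @ coef)
    return PLSModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        intercept=intercept,
        column_labels=M.column_labels,
        scale_factors=factors,
        train_rows=rows,
        meta={"scaling": M.scaling},
    )


def _coef_path(
    M: DescriptorMatrix, rows: np.ndarray, max_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and intercepts for every component count 1..c_max in one
    NIPALS pass (original column scale).  The path truncates early if the
    centered matrix runs out of rank; a fully degenerate row subset (no
    extractable component, e.g. an LOO fold whose remaining rows carry no
    descriptor variation) yields the intercept-only model at every count.
    """
    factors = M.scale_factors(rows)
    Xs = M.X_raw[rows] * factors
    x_mean = Xs.mean(axis=0)
    y_mean = float(M.y[rows].mean())
    limit = min(max_components, rows.size - 1, M.n_columns)
    W = P = q = None
    for c in range(limit, 0, -1):
        try:
            W, P, _T, q = _nipals(Xs - x_mean, M.y[rows] - y_mean, c)
            break
        except ValueError:
            continue
    if W is None:
        return (np.zeros((M.n_columns, limit)), np.full(limit, y_mean))
    reached = W.shape[1]
    coefs = np.zeros((M.n_columns, reached))
    intercepts = np.zeros(reached)
    raw_mean = M.X_raw[rows].mean(axis=0)
    for c in range(1, reached + 1):
        b = W[:, :c] @ np.linalg.solve(P[:, :c].T @ W[:, :c], q[:c])
        coefs[:, c - 1] = b * factors
        intercepts[c - 1] = y_mean - float(raw_mean @ coefs[:, c - 1])
    return coefs, intercepts


def _loo_predictions(M: DescriptorMatrix, max_components: int) -> np.ndarray:
    """(n_train, c_max) leave-one-out predictions.

    A fold whose effective rank falls short of a component count keeps its
    highest-rank model for the remaining counts.
    """
    rows = M.train_rows
    n = rows.size
    preds = np.full((n, max_components), np.nan)
    for pos in range(n):
        sub = np.delete(rows, pos)
        coefs, intercepts = _coef_path(M, sub, max_components)
        x = M.X_raw[rows[pos]]
        got = coefs.shape[1]
        preds[pos, :got] = x @ coefs[:, :got] + intercepts[:got]
        preds[pos, got:] = preds[pos, got - 1]
    return preds


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

def loo_q2(
    M: DescriptorMatrix, n_components: int
) -> tuple[float, float, float]:
    """Leave-one-out Q², SEP and PRESS over the training rows.

    Every fold refits centering and scaling on the remaining n−1 rows (the
    kept-column set stays frozen from assembly) and predicts the held-out
    activity; Q² compares PRESS with deviations from the full-training-set
    mean.
    """
    rows = M.train_rows
    n = rows.size
    if n < n_components + 2:
        raise ValueError("too few training molecules for LOO at this component count")
    y = M.y[rows]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("zero total sum of squares: constant activities")
    preds = _loo_predictions(M, n_components)[:, n_components - 1]
    press = float(((y - preds) ** 2).sum())
    q2 = 1.0 - press / ss_tot
    sep = math.sqrt(press / (n - n_components - 1))
    return q2, sep, press


def select_opn(
    M: DescriptorMatrix,
    max_components: int = 10,
    criterion: str = "q2",
) -> tuple[int, pd.DataFrame]:
    """Pick the optimum number of PLS components.

    Default criterion: maximum LOO Q², ties (within 1e−6) broken toward the
    smaller count.  ``min_see`` instead minimizes the fitted standard error
    of estimate.  The full per-component table (Q², SEP, SEE) is returned
    either way.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    rows_out = []
    limit = min(max_components, M.train_rows.size - 2, M.n_columns)
    rows = M.train_rows
    n = rows.size
    y = M.y[rows]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("zero total sum of squares: constant activities")
    preds = _loo_predictions(M, limit)
    full_coefs, full_intercepts = _coef_path(M, rows, limit)
    for c in range(1, limit + 1):
        col = preds[:, c - 1]
        if np.isnan(col).any() or c > full_coefs.shape[1]:
            break
        press = float(((y - col) ** 2).sum())
        q2 = 1.0 - press / ss_tot
        sep = math.sqrt(press / (n - c - 1))
        resid = y - (M.X_raw[rows] @ full_coefs[:, c - 1] + full_intercepts[c - 1])
        see = math.sqrt(float(resid @ resid) / (n - c - 1))
        rows_out.append({"components": c, "q2": q2, "sep": sep, "see": see})
    if not rows_out:
        raise ValueError("no component count could be evaluated")
    table = pd.DataFrame(rows_out)
    if criterion == "q2":
        best = table.loc[0]
        for _, row in table.iterrows():
            if row["q2"] > best["q2"] + 1e-6:
                best = row
        opn = int(best["components"])
    elif criterion == "min_see":
        best = table.loc[0]
        for _, row in table.iterrows():
            if row["see"] < best["see"] - 1e-6:
                best = row
        opn = int(best["components"])
    else:
        raise ValueError(f"unknown OPN criterion {criterion!r}")
    return opn, table


@dataclass
class ModelStats:
    """The per-model statistics block: internal and external validity."""

    q2: float
    sep: float
    press: float
    r2_ncv: float
    see: float
    f: float
    r2_pred: float | None
    opn: int
    contributions: dict[str, float]

    def as_dict(self) -> dict:
        d = {
            "Q2": self.q2,
            "SEP": self.sep,
            "R2_ncv": self.r2_ncv,
            "SEE": self.see,
            "F": self.f if math.isfinite(self.f) else "inf",
            "R2_pred": self.r2_pred,
            "OPN": self.opn,
            "contributions_pct": {k: 100.0 * v for k, v in self.contributions.items()},
        }
        return d


def final_stats(model: PLSModel, M: DescriptorMatrix) -> ModelStats:
    """Non-cross-validated statistics plus external prediction and the
    per-field contribution fractions (Σ|b_j|·sd_j per field, normalized)."""
    rows = model.train_rows
    n, c = rows.size, model.n_components
    y = M.y[rows]
    resid = y - model.predict(M.X_raw[rows])
    rss = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("zero total sum of squares: constant activities")
    r2 = 1.0 - rss / ss_tot
    see = math.sqrt(rss / (n - c - 1))
    f = math.inf if r2 >= 1.0 else (r2 / (1.0 - r2)) * ((n - c - 1) / c)

    test = M.test_rows
    r2_pred: float | None = None
    if test.size:
        y_test = M.y[test]
        pred = model.predict(M.X_raw[test])
        denom = float(((y_test - y.mean()) ** 2).sum())
        r2_pred = 1.0 - float(((y_test - pred) ** 2).sum()) / denom

    sd = M.X_raw[rows].std(axis=0, ddof=1)
    weight = np.abs(model.coef) * sd
    total = float(weight.sum())
    contributions = {}
    for kind in model.field_kinds:
        cols = M.columns_of_kind(kind)
        contributions[kind] = float(weight[cols].sum()) / total if total > 0 else 0.0

    q2, sep, press = loo_q2(M, c)
    return ModelStats(
        q2=q2, sep=sep, press=press, r2_ncv=r2, see=see, f=f,
        r2_pred=r2_pred, opn=c, contributions=contributions,
    )


# ---------------------------------------------------------------------------
# field-combination search
# ---------------------------------------------------------------------------

def subset_label(kinds: tuple[str, ...]) -> str:
    return "+".join(_SHORT_LABEL[k] for k in kinds)


def model_search(
    blocks: list[FieldBlock],
    y: np.ndarray,
    split_labels: np.ndarray | list[str] | None = None,
    max_components: int = 10,
    min_sigma: float | dict[str, float] | None = None,
    scaling: str = "block_standard",
    opn_criterion: str = "q2",
) -> tuple[pd.DataFrame, dict[str, tuple[PLSModel, DescriptorMatrix, ModelStats]]]:
    """Evaluate all 31 non-empty subsets of the five CoMSIA fields.

    Each subset gets its own matrix assembly, OPN selection and final
    statistics; the ranking is Q² descending, ties toward smaller OPN, then
    lexicographic subset label.  Fully deterministic.
    """
    kinds = [b.field_kind for b in blocks]
    if sorted(kinds) != sorted(COMSIA_KINDS):
        raise ValueError("model_search expects exactly the five CoMSIA blocks")
    by_kind = {b.field_kind: b for b in blocks}
    ordered = [by_kind[k] for k in COMSIA_KINDS]

    records = []
    fitted: dict[str, tuple[PLSModel, DescriptorMatrix, ModelStats]] = {}
    for r in range(1, 6):
        for combo in itertools.combinations(ordered, r):
            label = subset_label(tuple(b.field_kind for b in combo))
            M = assemble_matrix(
                list(combo), y, min_sigma=min_sigma, scaling=scaling,
                split_labels=split_labels,
            )
            opn, _table = select_opn(M, max_components, criterion=opn_criterion)
            model = pls_fit(M, opn)
            stats = final_stats(model, M)
            fitted[label] = (model, M, stats)
            records.append(
                {
                    "fields": label,
                    "OPN": opn,
                    "Q2": stats.q2,
                    "R2_ncv": stats.r2_ncv,
                    "SEE": stats.see,
                    "SEP": stats.sep,
                    "F": stats.f,
                    "R2_pred": stats.r2_pred,
                    **{
                        f"contrib_{_SHORT_LABEL[k]}": v
                        for k, v in stats.contributions.items()
                    },
                }
            )
    df = pd.DataFrame(records)
    df = df.sort_values(
        by=["Q2", "OPN", "fields"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df, fitted


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(
    molecules: list[Molecule],
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
    stratify: bool = True,
) -> list[Molecule]:
    """Randomly label molecules train/test at the given ratio.

    The training count is round(n · a/(a+b)).  With ``stratify`` (default)
    the shuffle runs within activity tertiles so the test set mirrors the
    activity distribution; allocation across tertiles uses largest
    remainders so the totals are exact.
    """
    n = len(molecules)
    if n < 3:
        raise ValueError("need at least 3 molecules to split")
    a, b = ratio
    frac = a / (a + b)
    n_train = int(math.floor(n * frac + 0.5))
    rng = np.random.default_rng(seed)

    activities = [m.activity_pIC50 for m in molecules]
    out = [m.copy() for m in molecules]
    if stratify and all(v is not None for v in activities):
        vals = np.array(activities, dtype=float)
        edges = np.quantile(vals, [1 / 3, 2 / 3])
        strata = np.digitize(vals, edges)
        strat_ids = sorted(set(strata))
        sizes = {s: int((strata == s).sum()) for s in strat_ids}
        base = {s: int(math.floor(sizes[s] * frac)) for s in strat_ids}
        leftover = n_train - sum(base.values())
        rema = sorted(
            strat_ids, key=lambda s: (-(sizes[s] * frac - base[s]), s)
        )
        for s in rema[:leftover]:
            base[s] += 1
        for s in strat_ids:
            idx = np.flatnonzero(strata == s)
            rng.shuffle(idx)
            for k, i in enumerate(idx):
                out[i].split_label = "train" if k < base[s] else "test"
    else:
        idx = np.arange(n)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            out[i].split_label = "train" if k < n_train else "test"
    return out
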