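"""Interactor selection from replicate SILAC quantifications.

The substrate is a per-protein table of heavy/light (H/L) intensities or
ratios over biological replicates (bait pull-down labeled heavy, control
pull-down light).  The screen computes a mean enrichment ratio and a p value
per protein and applies the selection filter used for bait-interactor
candidate lists: mean H/L ratio above a fold cutoff, at least a minimum
number of unique peptides, p below a cutoff, optionally an FDR criterion.

Two test modes are supported, mirroring the two descriptions that commonly
coexist for such screens:

* ``two_sided_unpaired_intensity`` (default): two-sided unpaired t-test on
  log-transformed heavy vs light intensities (pooled variance).
* ``one_tailed_log_ratio``: one-sample t-test of the replicate log2 ratios
  against 0, upper tail.

A permutation FDR (heavy/light label reassignment) and Benjamini-Hochberg
adjustment are available on top of either test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SilacTable",
    "SelectionCriteria",
    "load_silac_table",
    "load_table1_fixture",
    "compute_ratio_stats",
    "test_enrichment",
    "permutation_fdr",
    "select_interactors",
    "export_interactors",
]

#: smallest positive p reported for zero-variance, unequal-mean degeneracies
_P_DEGENERATE = np.nextafter(0.0, 1.0)

_ANNOT_COLS = ("gene", "name", "localization", "function")


@dataclass
class SilacTable:
    """A typed protein-level SILAC quantification table.

    ``df`` is indexed by ``protein_id``.  In *replicate* mode it carries
    ``rep{k}_H``/``rep{k}_L`` (or ``rep{k}_ratio``) columns plus
    ``uniq_peptides``; in *summary* mode it carries precomputed ``mean_ratio``
    and ``p_value`` columns (a published table taken as given).  Missing
    intensities stay as NaN.
    """

    df: pd.DataFrame
    n_replicates: int
    mode: str  # "intensity" | "ratio" | "summary"

    def __len__(self) -> int:
        return len(self.df)

    def replicate_ratios(self) -> pd.DataFrame:
        """Per-replicate H/L ratios (NaN where either intensity is missing/zero)."""
        if self.mode == "summary":
            raise ValueError("summary tables carry no replicate-level ratios")
        cols = {}
        for k in range(1, self.n_replicates + 1):
            if self.mode == "ratio":
                cols[f"rep{k}_ratio"] = self.df[f"rep{k}_ratio"]
            else:
                h = self.df[f"rep{k}_H"].astype(float)
                light = self.df[f"rep{k}_L"].astype(float)
                ratio = h / light
                ratio[(light <= 0) | (h < 0)] = np.nan
                cols[f"rep{k}_ratio"] = ratio
        return pd.DataFrame(cols, index=self.df.index)


def _detect_layout(columns: list[str]) -> tuple[str, int]:
    reps_h = sorted(int(c[3:-2]) for c in columns
                    if c.startswith("rep") and c.endswith("_H"))
    reps_r = sorted(int(c[3:-6]) for c in columns
                    if c.startswith("rep") and c.endswith("_ratio"))
    if reps_h:
        return "intensity", max(reps_h)
    if reps_r:
        return "ratio", max(reps_r)
    if "mean_ratio" in columns:
        return "summary", 0
    raise ValueError(
        "unrecognized SILAC table layout: need rep{k}_H/rep{k}_L, "
        "rep{k}_ratio, or mean_ratio columns"
    )


def load_silac_table(path: str | Path, *, dialect: str | None = None) -> SilacTable:
    """Load a CSV/TSV SILAC table.

    Header must contain ``protein_id`` plus either per-replicate
    ``rep{k}_H``/``rep{k}_L`` intensities, per-replicate ``rep{k}_ratio``
    columns, or summary ``mean_ratio``/``p_value`` columns.  Duplicate protein
    ids raise; malformed numeric fields raise naming the row; an empty file
    yields an empty table with a warning.
    """
    path = Path(path)
    sep = dialect if dialect in (",", "\t") else (
        "\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"protein_id": str})
    if df.empty:
        warnings.warn(f"{path}: empty SILAC table", stacklevel=2)
        return SilacTable(df.set_index("protein_id") if "protein_id" in df
                          else df, 0, "summary")
    if "protein_id" not in df.columns:
        raise ValueError(f"{path}: missing protein_id column")
    dup = df["protein_id"][df["protein_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate protein ids: {sorted(set(dup))}")
    mode, n_reps = _detect_layout(list(df.columns))
    num_cols = [c for c in df.columns
                if c.startswith("rep") or c in ("mean_ratio", "p_value",
                                                "uniq_peptides")]
    for c in num_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()
                     & df[c].notna()]["protein_id"]
            raise ValueError(
                f"{path}: malformed numeric field in column {c!r}, "
                f"rows {list(bad)[:5]}"
            ) from exc
    return SilacTable(df.set_index("protein_id"), n_reps, mode)


def load_table1_fixture() -> SilacTable:
    """Load the packaged 78-row published interactor table (bait included)."""
    with resources.as_file(
        resources.files("epitrack").joinpath("data/table1_epcam_interactors.tsv")
    ) as p:
        return load_silac_table(p)


# ---------------------------------------------------------------------------
# Per-protein statistics
# ---------------------------------------------------------------------------

def compute_ratio_stats(table: SilacTable, *, geometric: bool = False) -> pd.DataFrame:
    """Attach mean ratio and log2 ratios per protein.

    The mean ratio is the arithmetic mean of the available replicate ratios
    (geometric-mean mode behind the flag).  Proteins with zero usable
    replicate ratios are flagged ``no_usable_replicates`` and carry NaN.
    Returns a stats DataFrame indexed like the table.
    """
    if table.mode == "summary":
        out = table.df.copy()
        out["n_quantified"] = table.n_replicates
        out["no_usable_replicates"] = out["mean_ratio"].isna()
        return out
    ratios = table.replicate_ratios()
    log2r = np.log2(ratios)
    if geometric:
        mean_ratio = np.exp2(log2r.mean(axis=1, skipna=True))
    else:
        mean_ratio = ratios.mean(axis=1, skipna=True)
    out = pd.DataFrame(index=table.df.index)
    if "gene" in table.df:
        out["gene"] = table.df["gene"]
    out["mean_ratio"] = mean_ratio
    out["uniq_peptides"] = table.df.get("uniq_peptides")
    for c in log2r.columns:
        out[c.replace("_ratio", "_log2ratio")] = log2r[c]
    out["n_quantified"] = ratios.notna().sum(axis=1)
    out["no_usable_replicates"] = out["n_quantified"] == 0
    return out


def test_enrichment(table: SilacTable,
                    test: str = "two_sided_unpaired_intensity") -> pd.Series:
    """Per-protein enrichment p value under the chosen test mode.

    ``two_sided_unpaired_intensity``: pooled two-sided t on log heavy vs log
    light intensities.  ``one_tailed_log_ratio``: one-sample upper-tail t of
    log2 ratios against 0.  Zero variance with equal group means gives p = 1;
    zero variance with unequal means gives the smallest positive float and a
    ``degenerate`` flag in the returned Series' attrs.
    """
    t_stat, p, degenerate = _enrichment_statistics(table, test)
    out = pd.Series(p, index=table.df.index, name="p_value")
    out.attrs["t_statistic"] = pd.Series(t_stat, index=table.df.index)
    out.attrs["degenerate"] = pd.Series(degenerate, index=table.df.index)
    return out


def _log_intensity_groups(table: SilacTable) -> tuple[np.ndarray, np.ndarray]:
    hcols = [f"rep{k}_H" for k in range(1, table.n_replicates + 1)]
    lcols = [f"rep{k}_L" for k in range(1, table.n_replicates + 1)]
    H = np.log(table.df[hcols].to_numpy(dtype=float))
    L = np.log(table.df[lcols].to_numpy(dtype=float))
    return H, L


def _pooled_t_two_sided(H: np.ndarray, L: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sided unpaired t-test along axis 1."""
    nh = np.sum(np.isfinite(H), axis=1)
    nl = np.sum(np.isfinite(L), axis=1)
    mh = np.nanmean(H, axis=1)
    ml = np.nanmean(L, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vh = np.nanvar(H, axis=1, ddof=1)
        vl = np.nanvar(L, axis=1, ddof=1)
    df = nh + nl - 2
    sp2 = ((nh - 1) * vh + (nl - 1) * vl) / np.where(df > 0, df, 1)
    se = np.sqrt(sp2 * (1.0 / nh + 1.0 / nl))
    diff = mh - ml
    degenerate = (se == 0) & (diff != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    p = np.where(degenerate, _P_DEGENERATE, p)
    with np.errstate(invalid="ignore"):
        t = np.where(se == 0,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return t, np.minimum(p, 1.0), degenerate


def _one_sample_t_upper(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-sample upper-tail t of log2 ratios against 0."""
    n = np.sum(np.isfinite(X), axis=1)
    m = np.nanmean(X, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanstd(X, axis=1, ddof=1)
    se = s / np.sqrt(n)
    degenerate = (se == 0) & (m != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / se
    p = stats.t.sf(t, np.maximum(n - 1, 1))
    p = np.where((se == 0) & (m == 0), 1.0, p)
    p = np.where(degenerate, np.where(m > 0, _P_DEGENERATE, 1.0), p)
    t = np.where(se == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)
    return t, np.minimum(p, 1.0), degenerate


def _enrichment_statistics(table: SilacTable, test: str):
    if table.mode == "summary":
        raise ValueError("summary tables carry published p values; nothing to test")
    if table.n_replicates < 2:
        raise ValueError("need >= 2 replicates for testing")
    if test == "two_sided_unpaired_intensity":
        if table.mode != "intensity":
            raise ValueError("intensity test needs rep{k}_H/rep{k}_L columns")
        return _pooled_t_two_sided(*_log_intensity_groups(table))
    if test == "one_tailed_log_ratio":
        X = np.log2(table.replicate_ratios().to_numpy(dtype=float))
        return _one_sample_t_upper(X)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

def permutation_fdr(table: SilacTable, *, n_null: int = 500, seed: int = 0,
                    exhaustive_cap: int = 64,
                    test: str = "two_sided_unpaired_intensity") -> pd.Series:
    """Permutation-based q values from heavy/light label reassignment.

    The 2k per-protein intensities are relabeled into pseudo-heavy/pseudo-light
    halves; when the number of balanced assignments C(2k, k) is at most
    ``exhaustive_cap`` all of them are used (20 for k = 3), otherwise
    ``n_null`` random assignments.  q(protein) = (mean null count of proteins
    with statistic >= observed) / (observed count with statistic >= observed),
    capped at 1 and monotonized in the observed statistic.
    """
    if table.mode != "intensity":
        raise ValueError("permutation FDR needs the intensity-mode test")
    if table.n_replicates < 2:
        raise ValueError("need >= 2 replicates for permutation FDR")
    H, L = _log_intensity_groups(table)
    X = np.concatenate([H, L], axis=1)  # (P, 2k)
    k = table.n_replicates
    two_sided = test == "two_sided_unpaired_intensity"

    obs_t, _, _ = (_pooled_t_two_sided(H, L) if two_sided
                   else _one_sample_t_upper(np.log2(np.exp(H - L))))
    obs = np.abs(obs_t) if two_sided else obs_t

    combos = list(itertools.combinations(range(2 * k), k))
    rng = np.random.default_rng(seed)
    if len(combos) > exhaustive_cap:
        idx = rng.choice(len(combos), size=min(n_null, len(combos)), replace=False)
        combos = [combos[i] for i in idx]

    null_stats = []
    all_idx = set(range(2 * k))
    for combo in combos:
        rest = sorted(all_idx - set(combo))
        Hp, Lp = X[:, list(combo)], X[:, rest]
        t_null, _, _ = (_pooled_t_two_sided(Hp, Lp) if two_sided
                        else _one_sample_t_upper(np.log2(np.exp(Hp - Lp))))
        null_stats.append(np.abs(t_null) if two_sided else t_null)
    null = np.concatenate(null_stats)
    null = null[np.isfinite(null)]

    order = np.argsort(-obs)  # descending by statistic
    q = np.full(obs.shape, np.nan)
    n_perm = len(combos)
    sorted_null = np.sort(null)
    for rank, i in enumerate(order, start=1):
        if not np.isfinite(obs[i]):
            q[i] = 1.0 if np.isnan(obs[i]) else 0.0
            continue
        n_null_ge = len(sorted_null) - np.searchsorted(sorted_null, obs[i], "left")
        q[i] = min((n_null_ge / n_perm) / rank, 1.0)
    # monotonize: q non-increasing in the statistic
    running = 1.0
    for i in order[::-1]:
        running = min(running, q[i])
        q[i] = running
    return pd.Series(q, index=table.df.index, name="q_value")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionCriteria:
    """The interactor selection filter.

    Defaults reproduce the published criteria: mean H/L ratio > 3, p <= 0.05,
    >= 2 unique peptides, quantified in all replicates.  ``per_replicate_fold``
    switches on the strict reading in which every single replicate ratio must
    clear the fold cutoff.
    """

    min_fold: float = 3.0
    max_p: float = 0.05
    min_unique_peptides: int = 2
    require_all_replicates: bool = True
    per_replicate_fold: bool = False
    test: str = "two_sided_unpaired_intensity"
    fdr: str = "none"  # none | permutation | benjamini_hochberg
    fdr_threshold: float = 0.05

    def validate(self) -> None:
        if not self.min_fold > 0:
            raise ValueError("min_fold must be > 0")
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")


def select_interactors(table: SilacTable,
                       criteria: SelectionCriteria | None = None,
                       *, seed: int = 0) -> pd.DataFrame:
    """Apply the selection filter; return the full audit table.

    The returned DataFrame carries per-protein ``mean_ratio``, ``p_value``,
    optional ``q_value``, ``uniq_peptides``, per-criterion ``pass_*`` flags
    and the combined ``selected`` flag.  Retained proteins are the rows with
    ``selected``; the bait is treated like any other protein.
    """
    criteria = criteria or SelectionCriteria()
    criteria.validate()
    stats_df = compute_ratio_stats(table)
    if table.mode == "summary":
        if "p_value" not in stats_df:
            raise ValueError("summary table lacks a p_value column")
        out = stats_df.copy()
    else:
        out = stats_df.copy()
        p = test_enrichment(table, criteria.test)
        out["p_value"] = p
        out["degenerate_test"] = p.attrs["degenerate"].to_numpy()
        if criteria.fdr == "permutation":
            out["q_value"] = permutation_fdr(table, seed=seed, test=criteria.test)
        elif criteria.fdr == "benjamini_hochberg":
            from statsmodels.stats.multitest import multipletests
            mask = out["p_value"].notna()
            q = pd.Series(np.nan, index=out.index)
            if mask.any():
                q[mask] = multipletests(out.loc[mask, "p_value"],
                                        method="fdr_bh")[1]
            out["q_value"] = q

    if criteria.per_replicate_fold and table.mode != "summary":
        ratios = table.replicate_ratios()
        out["pass_fold"] = (ratios > criteria.min_fold).all(axis=1) \
            & ratios.notna().all(axis=1)
    else:
        out["pass_fold"] = out["mean_ratio"] > criteria.min_fold
    out["pass_p"] = out["p_value"] <= criteria.max_p
    if "uniq_peptides" in out.columns:
        out["pass_peptides"] = out["uniq_peptides"] >= criteria.min_unique_peptides
    else:
        raise ValueError("criteria reference unique peptides but the table "
                         "has no uniq_peptides column")
    out["pass_replicates"] = True
    if criteria.require_all_replicates and table.mode != "summary":
        out["pass_replicates"] = out["n_quantified"] == table.n_replicates
    out["pass_fdr"] = True
    if criteria.fdr != "none" and "q_value" in out:
        out["pass_fdr"] = out["q_value"] <= criteria.fdr_threshold

    out["selected"] = (out["pass_fold"] & out["pass_p"] & out["pass_peptides"]
                       & out["pass_replicates"] & out["pass_fdr"])
    return out


def export_interactors(interactors: pd.DataFrame, path: str | Path,
                       *, selected_only: bool = True) -> Path:
    """Write the interactor set as TSV with a stable column order."""
    path = Path(path)
    df = interactors[interactors["selected"]] if selected_only else interactors
    lead = ["mean_ratio", "uniq_peptides"]
    annot = [c for c in _ANNOT_COLS if c in df.columns]
    stats_cols = [c for c in ("p_value", "q_value") if c in df.columns]
    flags = [c for c in df.columns if c.startswith("pass_")] + ["selected"]
    cols = lead + annot + stats_cols + [c for c in flags if c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", index=True, index_label="protein_id")
    return path
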