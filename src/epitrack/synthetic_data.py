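"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis stage assumes:

* :func:`simulate_silac_screen` — replicate heavy/light (H/L) ratio tables with
  a planted set of true interactors over a log-normal null background, matching
  a three-replicate SILAC AP-MS screen design.
* :func:`simulate_flow_panel` — per-cell fluorescence for the five groups of an
  antibody-quench internalization/recycling assay (unstained, 100 % labeled,
  quench background, endocytosis, recycling).
* :func:`simulate_timecourse` — endocytosis-group panels along a time axis with
  a supplied internalized-fraction curve e(t).
* :func:`simulate_colocalization_images` — two-channel Gaussian-spot images
  with a planted channel-B-on-channel-A intensity-overlap fraction.
* :func:`simulate_qpcr` — Ct tables with planted per-group log2 fold changes
  relative to a housekeeping gene.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; no global RNG state is touched.  Identical
parameters and seed give byte-identical serialized outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SilacSimParams",
    "TraffickingParams",
    "ColocSimParams",
    "QpcrSimParams",
    "FLOW_GROUPS",
    "simulate_silac_screen",
    "simulate_flow_panel",
    "simulate_timecourse",
    "simulate_colocalization_images",
    "simulate_qpcr",
]

FLOW_GROUPS = ("unstained", "labeled_100", "quench_bg", "endocytosis", "recycling")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(*values: float) -> bool:
    return all(math.isfinite(float(v)) for v in values)


# ---------------------------------------------------------------------------
# SILAC screen
# ---------------------------------------------------------------------------

@dataclass
class SilacSimParams:
    """Design of a simulated SILAC pull-down screen.

    Defaults mirror a three-replicate bait-vs-control design with a strong
    (8-fold) planted enrichment and moderate multiplicative noise, the regime
    in which the published screen operated.
    """

    n_background: int = 500
    n_true: int = 40
    true_log2_fold: float = 3.0          # log2 of planted H/L enrichment (8-fold)
    ratio_sd: float = 0.3                # per-replicate log2 noise
    n_replicates: int = 3
    peptide_geom_p: float = 0.3          # unique peptides ~ 1 + Geometric(p)
    intensity_scale: float = 1e7
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_replicates >= 2, "n_replicates must be >= 2")
        _require(self.ratio_sd > 0 or self.ratio_sd == 0, "ratio_sd must be >= 0")
        _require(0 < self.peptide_geom_p < 1, "peptide_geom_p must be in (0, 1)")
        _require(self.n_background >= 0 and self.n_true >= 0, "counts must be >= 0")
        _require(
            _finite(self.true_log2_fold, self.ratio_sd, self.intensity_scale),
            "parameters must be finite",
        )
        _require(self.intensity_scale > 0, "intensity_scale must be > 0")


def simulate_silac_screen(params: SilacSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a replicate H/L intensity table plus its ground-truth labels.

    Returns ``(table, truth)``: *table* has columns ``protein_id, gene,
    uniq_peptides, rep{k}_H, rep{k}_L`` and *truth* maps ``protein_id`` to
    ``is_true_interactor``.

    Heavy and light channels are measured independently (separate pull-downs),
    each with log2 noise ``ratio_sd / sqrt(2)`` around a shared per-protein
    abundance, so per-replicate log2 ratios are exactly ``Normal(0, ratio_sd)``
    for background proteins and ``Normal(true_log2_fold, ratio_sd)`` for
    planted interactors, and the two intensity groups are independent with
    equal variance — the regime the pooled unpaired t-test assumes.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n = params.n_background + params.n_true
    ids = [f"SIM{i:05d}" for i in range(n)]
    is_true = np.zeros(n, dtype=bool)
    is_true[params.n_background:] = True

    mu = np.where(is_true, params.true_log2_fold, 0.0)
    # per-protein abundance (constant across replicates and channels: does not
    # enter any within-protein contrast)
    abundance = rng.normal(0.0, 1.0, size=n)
    chan_sd = params.ratio_sd / math.sqrt(2.0)
    shape = (n, params.n_replicates)
    log2_light = abundance[:, None] + rng.normal(0.0, chan_sd, size=shape)
    log2_heavy = (abundance[:, None] + mu[:, None]
                  + rng.normal(0.0, chan_sd, size=shape))
    light = params.intensity_scale * np.exp2(log2_light)
    heavy = params.intensity_scale * np.exp2(log2_heavy)
    peptides = 1 + rng.geometric(params.peptide_geom_p, size=n)

    data: dict[str, object] = {
        "protein_id": ids,
        "gene": [f"Gene{i}" for i in range(n)],
        "uniq_peptides": peptides,
    }
    for k in range(params.n_replicates):
        data[f"rep{k + 1}_H"] = heavy[:, k]
        data[f"rep{k + 1}_L"] = light[:, k]
    table = pd.DataFrame(data)
    truth = pd.DataFrame({"protein_id": ids, "is_true_interactor": is_true})
    return table, truth


# ---------------------------------------------------------------------------
# Flow-cytometry trafficking assay
# ---------------------------------------------------------------------------

@dataclass
class TraffickingParams:
    """Generative model of the antibody-quench endocytosis/recycling assay.

    Per cell, autofluorescence ``A`` and surface label ``S`` are log-normal.
    ``quench_eff`` (q) is the fraction of surface-exposed fluorescence removed
    per quench application; ``endo_frac`` (e) the fraction of the labeled
    surface pool internalized in the first window; ``recycle_frac`` (r) the
    fraction of the internal pool returned to the surface (and re-quenched)
    during the chase; ``ongoing_internalization_frac`` (f) the fraction of the
    surface pool internalized during the chase, with internalized quenched
    label regaining fluorescence (quench-antibody dissociation in acidic
    endosomes) — the mechanism behind apparently negative recycling.
    """

    n_cells_per_group: int = 10_000
    surface_mu: float = math.log(1000.0)   # log-normal location of S
    surface_sigma: float = 0.4
    autofluor_mu: float = math.log(50.0)   # log-normal location of A
    autofluor_sigma: float = 0.3
    quench_eff: float = 0.95
    endo_frac: float = 0.0825              # mF9-like endocytosed fraction
    recycle_frac: float = 0.60             # mF9-like recycled fraction
    ongoing_internalization_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_cells_per_group >= 1, "n_cells_per_group must be >= 1")
        for name in ("quench_eff", "endo_frac", "recycle_frac",
                     "ongoing_internalization_frac"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must be in [0, 1]")
        _require(
            _finite(self.surface_mu, self.surface_sigma,
                    self.autofluor_mu, self.autofluor_sigma),
            "scale parameters must be finite",
        )
        _require(self.surface_sigma >= 0 and self.autofluor_sigma >= 0,
                 "sigmas must be >= 0")


def _expected_fl1(A: np.ndarray, S: np.ndarray, group: str, q: float, e: float,
                  r: float, f: float) -> np.ndarray:
    """Per-cell fluorescence of each assay group under the quench model."""
    if group == "unstained":
        return A.copy()
    if group == "labeled_100":
        return A + S
    if group == "quench_bg":
        return A + (1.0 - q) * S
    if group == "endocytosis":
        return A + (1.0 - q) * (1.0 - e) * S + e * S
    if group == "recycling":
        # surface residual not internalized during the chase is quenched again;
        # the fraction f internalized during the chase dequenches (f*(1-e)*S
        # total: its unquenched part stays bright, its quenched part recovers);
        # recycled internal label returns to the surface and is re-quenched.
        return (
            A
            + (1.0 - q) ** 2 * (1.0 - e) * (1.0 - f) * S
            + f * (1.0 - e) * S
            + (1.0 - q) * e * r * S
            + e * (1.0 - r) * S
        )
    raise ValueError(f"unknown group {group!r}")


def simulate_flow_panel(
    params: TraffickingParams,
    *,
    timepoint_min: float | None = None,
    groups: Sequence[str] = FLOW_GROUPS,
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Simulate an event table for the five assay groups.

    Returns a DataFrame with columns ``sample_id, group, timepoint_min, fsc,
    ssc, fl1``.  Scatter channels are tight normals so essentially all events
    fall inside any sensible live gate.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    q, e, r, f = (params.quench_eff, params.endo_frac,
                  params.recycle_frac, params.ongoing_internalization_frac)
    n = params.n_cells_per_group

    frames = []
    for group in groups:
        if group not in FLOW_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        A = np.exp(rng.normal(params.autofluor_mu, params.autofluor_sigma, n))
        S = np.exp(rng.normal(params.surface_mu, params.surface_sigma, n))
        fl1 = _expected_fl1(A, S, group, q, e, r, f)
        fsc = rng.normal(50_000.0, 3_000.0, n)
        ssc = rng.normal(30_000.0, 2_500.0, n)
        frames.append(pd.DataFrame({
            "sample_id": sample_id,
            "group": group,
            "timepoint_min": np.nan if timepoint_min is None else timepoint_min,
            "fsc": fsc,
            "ssc": ssc,
            "fl1": fl1,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_timecourse(
    params: TraffickingParams,
    timepoints: Sequence[float],
    endo_rate_curve: Callable[[float], float],
) -> list[pd.DataFrame]:
    """One endocytosis-group panel per timepoint with e = e(t).

    The unstained/100 %-labeled/quench-background groups are shared across
    timepoints (simulated once, at the first timepoint's table); each
    subsequent table contains only the endocytosis group for its timepoint.
    e(t) must be a non-decreasing probability of t.
    """
    params.validate()
    es = [float(endo_rate_curve(t)) for t in timepoints]
    for t, e in zip(timepoints, es):
        _require(0.0 <= e <= 1.0, f"e({t}) = {e} outside [0, 1]")
    _require(all(b >= a - 1e-12 for a, b in zip(es, es[1:])),
             "endo_rate_curve must be non-decreasing")

    tables = []
    for i, (t, e) in enumerate(zip(timepoints, es)):
        p = TraffickingParams(**{**params.__dict__, "endo_frac": e,
                                 "seed": params.seed + i})
        groups = FLOW_GROUPS if i == 0 else ("endocytosis",)
        tables.append(simulate_flow_panel(p, timepoint_min=t, groups=groups))
    return tables


# ---------------------------------------------------------------------------
# Colocalization images
# ---------------------------------------------------------------------------

@dataclass
class ColocSimParams:
    """Two-channel Gaussian-spot images with a planted overlap fraction.

    ``overlap_frac`` is the fraction of channel-B spots centred on
    channel-A-positive pixels; with zero background and noise it equals (to
    one-spot granularity) the fraction of channel-B integrated intensity on
    channel-A-positive pixels, i.e. the Manders M2 coefficient with channel A
    as the reference.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_spots_a: int = 40
    n_spots_b: int = 40
    overlap_frac: float = 0.4
    spot_sigma: float = 1.5
    background_level: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        _require(h > 0 and w > 0, "image_shape must be positive")
        _require(0.0 <= self.overlap_frac <= 1.0, "overlap_frac must be in [0, 1]")
        _require(self.spot_sigma > 0, "spot_sigma must be > 0")
        _require(self.background_level >= 0 and self.noise_sd >= 0,
                 "background and noise must be >= 0")


def _stamp_spot(img: np.ndarray, cy: int, cx: int, sigma: float,
                amplitude: float, radius: int) -> None:
    h, w = img.shape
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, h)
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2)
    )


def simulate_colocalization_images(
    params: ColocSimParams,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Return ``(channel_a, channel_b, truth_overlap)`` as 16-bit arrays.

    Spot centres are laid on a jittered grid so spots from different sites do
    not touch; ``round(overlap_frac * n_spots_b)`` B spots are placed exactly
    on A spot centres, the rest on free sites.  ``truth_overlap`` is the
    realized fraction of B spots sharing an A site (== planted fraction up to
    one-spot granularity).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    radius = max(int(math.ceil(4 * params.spot_sigma)), 2)
    pitch = 2 * radius + 3  # site spacing: spots at distinct sites never touch

    sites_y = np.arange(radius + 1, h - radius - 1, pitch)
    sites_x = np.arange(radius + 1, w - radius - 1, pitch)
    sites = [(int(y), int(x)) for y in sites_y for x in sites_x]
    n_coloc = int(round(params.overlap_frac * params.n_spots_b))
    n_sites_needed = params.n_spots_a + (params.n_spots_b - n_coloc)
    if n_sites_needed > len(sites):
        raise ValueError(
            f"too many spots for image area: need {n_sites_needed} sites, "
            f"have {len(sites)}"
        )
    if n_coloc > params.n_spots_a:
        raise ValueError("overlap_frac * n_spots_b exceeds n_spots_a: not "
                         "enough A spots to colocalize with")
    order = rng.permutation(len(sites))
    a_sites = [sites[i] for i in order[: params.n_spots_a]]
    free_sites = [sites[i] for i in order[params.n_spots_a: n_sites_needed]]

    chan_a = np.zeros((h, w), dtype=float)
    chan_b = np.zeros((h, w), dtype=float)
    amp = 1000.0
    for cy, cx in a_sites:
        _stamp_spot(chan_a, cy, cx, params.spot_sigma, amp, radius)
    coloc_idx = rng.choice(params.n_spots_a, size=n_coloc, replace=False)
    for i in coloc_idx:
        cy, cx = a_sites[i]
        _stamp_spot(chan_b, cy, cx, params.spot_sigma, amp, radius)
    for cy, cx in free_sites:
        _stamp_spot(chan_b, cy, cx, params.spot_sigma, amp, radius)

    for img in (chan_a, chan_b):
        img += params.background_level
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
        np.clip(img, 0.0, 65535.0, out=img)

    truth = n_coloc / params.n_spots_b if params.n_spots_b else 0.0
    return chan_a.astype(np.uint16), chan_b.astype(np.uint16), truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

@dataclass
class QpcrSimParams:
    """Ct tables with planted per-gene, per-group log2 expression changes.

    ``group_log2_fold[gene][group]`` is the planted log2 change of *gene* in
    *group* relative to the reference group; the housekeeping gene must have
    fold 0 everywhere.  Ct = baseline - log2(expression) + Normal(0, ct_sd).
    """

    genes: Sequence[str] = ("GUSB", "Sox2", "Vimentin")
    housekeeping: str = "GUSB"
    groups: Sequence[str] = ("D0", "D5")
    group_log2_fold: dict = field(default_factory=lambda: {
        "Sox2": {"D0": 0.0, "D5": -3.0},
        "Vimentin": {"D0": 0.0, "D5": 2.0},
    })
    baseline_ct: float = 25.0
    ct_sd: float = 0.15
    n_technical: int = 3
    n_biological: int = 3
    seed: int = 0

    def validate(self) -> None:
        _require(self.ct_sd >= 0, "ct_sd must be >= 0")
        _require(self.n_technical >= 1 and self.n_biological >= 1,
                 "replicate counts must be >= 1")
        _require(self.housekeeping in self.genes,
                 "housekeeping gene must be among genes")
        hk = self.group_log2_fold.get(self.housekeeping, {})
        _require(all(v == 0.0 for v in hk.values()),
                 "housekeeping gene must have log2 fold 0 in all groups")


def simulate_qpcr(params: QpcrSimParams) -> pd.DataFrame:
    """Simulate a Ct table: ``sample_id, group, gene, tech_rep, ct``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []
    for group in params.groups:
        for b in range(params.n_biological):
            sample = f"{group}_s{b + 1}"
            # per-sample loading offset, cancelled by housekeeping normalization
            offset = rng.normal(0.0, 0.3)
            for gene in params.genes:
                fold = params.group_log2_fold.get(gene, {}).get(group, 0.0)
                true_ct = params.baseline_ct - fold + offset
                for t in range(params.n_technical):
                    ct = true_ct + (rng.normal(0.0, params.ct_sd)
                                    if params.ct_sd > 0 else 0.0)
                    rows.append((sample, group, gene, t + 1, ct))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene", "tech_rep", "ct"]
    )
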