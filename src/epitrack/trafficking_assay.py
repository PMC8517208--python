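"""Endocytosis and membrane-recycling quantification from flow cytometry.

The antibody-quench assay measures five groups of cells: ``unstained``
(autofluorescence), ``labeled_100`` (fully surface-labeled), ``quench_bg``
(labeled then immediately quenched: residual unquenched surface signal),
``endocytosis`` (internalize, then quench: protected internal signal plus
residual), and ``recycling`` (internalize, quench, chase, quench again).

MFI normalization chain: every group's mean fluorescence intensity (MFI) is
normalized against the unstained control, then the (unstained-normalized)
quench background is subtracted, giving net MFIs

    net(g) = [MFI(g) - MFI(unstained)] - [MFI(quench_bg) - MFI(unstained)]
           = MFI(g) - MFI(quench_bg).

Rates:

    endocytosis_rate = net(endocytosis) / net(labeled_100)
    recycling_rate   = (net(endocytosis) - net(recycling)) / net(endocytosis)

The recycling sign convention deserves care: the literature formula
(net(recycling) - net(endocytosis)) / net(endocytosis) is negative for true
recycling under any quench-on-return model (recycled label returns to the
surface and is quenched, so the recycling arm can only lose protected
signal).  The default ``positive_recycling`` convention flips the sign so
that positive numbers mean recycling; the as-printed value is always reported
alongside, and every report logs the discrepancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import FLOW_GROUPS

__all__ = [
    "LiveGate",
    "AssayPanel",
    "gate_live",
    "mfi",
    "normalize_panel",
    "endocytosis_rate",
    "recycling_rate",
    "rate_standard_errors",
    "mfi_ratio",
    "timecourse_summary",
    "analyze_panel",
]


@dataclass
class LiveGate:
    """Rectangular FSC/SSC live-cell gate (absolute or percentile bounds)."""

    fsc_low: float = 1.0
    fsc_high: float = 99.0
    ssc_low: float = 1.0
    ssc_high: float = 99.0
    percentile: bool = True

    def validate(self) -> None:
        if not (self.fsc_low < self.fsc_high and self.ssc_low < self.ssc_high):
            raise ValueError("gate lower bounds must be below upper bounds")


def gate_live(events: pd.DataFrame, gate: LiveGate | None = None) -> pd.DataFrame:
    """Retain events inside the gate; retention fraction in ``attrs``.

    Default gate: 1st-99th percentile rectangle on FSC and SSC (per the
    convention that unreported gates are approximated by a permissive
    percentile rectangle).  Zero retained events raise.
    """
    gate = gate or LiveGate()
    gate.validate()
    if gate.percentile:
        f_lo, f_hi = np.percentile(events["fsc"], [gate.fsc_low, gate.fsc_high])
        s_lo, s_hi = np.percentile(events["ssc"], [gate.ssc_low, gate.ssc_high])
    else:
        f_lo, f_hi = gate.fsc_low, gate.fsc_high
        s_lo, s_hi = gate.ssc_low, gate.ssc_high
    keep = (events["fsc"].between(f_lo, f_hi)
            & events["ssc"].between(s_lo, s_hi))
    gated = events[keep].copy()
    if gated.empty:
        raise ValueError("live gate retained zero events")
    gated.attrs["retention"] = float(keep.mean())
    return gated


def mfi(events: pd.DataFrame | np.ndarray, channel: str = "fl1",
        *, geometric: bool = False) -> float:
    """Mean fluorescence intensity of a channel (geometric mean behind a flag)."""
    x = (np.asarray(events, dtype=float) if not isinstance(events, pd.DataFrame)
         else events[channel].to_numpy(dtype=float))
    if x.size == 0:
        raise ValueError("MFI of an empty event set is undefined")
    if geometric:
        if np.any(x <= 0):
            raise ValueError("geometric MFI needs strictly positive values")
        return float(np.exp(np.mean(np.log(x))))
    return float(x.mean())


@dataclass
class AssayPanel:
    """Per-group raw/normalized/net MFIs and derived rates."""

    raw_mfi: dict
    unstained_normalized: dict
    net_mfi: dict
    n_events: dict = field(default_factory=dict)
    group_var: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def normalize_panel(mfis: dict, *, n_events: dict | None = None,
                    group_var: dict | None = None) -> AssayPanel:
    """Apply the unstained-then-quench-background normalization chain.

    ``mfis`` maps the five group names to raw MFIs; the quench-background
    group itself is only unstained-normalized.  Negative net MFIs are
    permitted and flagged.  A missing group raises naming it.
    """
    missing = [g for g in FLOW_GROUPS if g not in mfis]
    if missing:
        raise ValueError(f"missing assay group(s): {missing}")
    uns = mfis["unstained"]
    qbg = mfis["quench_bg"]
    unstained_norm = {g: mfis[g] - uns for g in FLOW_GROUPS if g != "unstained"}
    net = {g: mfis[g] - qbg for g in ("labeled_100", "endocytosis", "recycling")}
    flags = [f"negative net MFI in {g}" for g, v in net.items() if v < 0]
    return AssayPanel(dict(mfis), unstained_norm, net,
                      n_events=dict(n_events or {}),
                      group_var=dict(group_var or {}), flags=flags)


def endocytosis_rate(panel: AssayPanel) -> float:
    """net(endocytosis) / net(labeled_100); may leave [0,1] under noise."""
    net_100 = panel.net_mfi["labeled_100"]
    if net_100 <= 0:
        raise ValueError(
            "net MFI of the 100% labeled control is <= 0; the panel has no "
            "measurable surface label and rates are undefined")
    rate = panel.net_mfi["endocytosis"] / net_100
    if not 0.0 <= rate <= 1.0:
        panel.flags.append(f"endocytosis rate {rate:.4f} outside [0, 1]")
    return float(rate)


def recycling_rate(panel: AssayPanel,
                   sign_convention: str = "positive_recycling") -> float:
    """Recycled fraction of the internalized pool.

    ``positive_recycling`` (default): (net(endo) - net(rec)) / net(endo), so
    positive output means label left the protected pool, i.e. recycling.
    ``as_printed``: (net(rec) - net(endo)) / net(endo), the literature
    formula, which is the negative of the former.
    """
    net_endo = panel.net_mfi["endocytosis"]
    if net_endo == 0:
        raise ValueError("net MFI of the endocytosis group is zero; "
                         "recycling rate is undefined")
    printed = (panel.net_mfi["recycling"] - net_endo) / net_endo
    if sign_convention == "as_printed":
        return float(printed)
    if sign_convention == "positive_recycling":
        return float(-printed)
    raise ValueError(f"unknown sign convention {sign_convention!r}")


def rate_standard_errors(panel: AssayPanel) -> dict:
    """Delta-method standard errors of both rates from per-group variances.

    Requires ``group_var`` (per-group event variance of FL1) and ``n_events``
    on the panel; group means are independent across groups.
    """
    if not panel.group_var or not panel.n_events:
        raise ValueError("panel lacks per-group variances / event counts")
    v = {g: panel.group_var[g] / panel.n_events[g]
         for g in ("labeled_100", "quench_bg", "endocytosis", "recycling")}
    x = panel.net_mfi["endocytosis"]   # numerator of endo rate
    y = panel.net_mfi["labeled_100"]
    # endo rate R = (m_e - m_qb)/(m_100 - m_qb)
    se_endo = np.sqrt(
        v["endocytosis"] / y**2
        + v["labeled_100"] * (x / y**2) ** 2
        + v["quench_bg"] * ((x - y) / y**2) ** 2
    )
    # recycling (positive convention) R = (m_e - m_rec)/(m_e - m_qb)
    a = panel.net_mfi["endocytosis"] - panel.net_mfi["recycling"]
    b = panel.net_mfi["endocytosis"]
    se_rec = np.sqrt(
        v["recycling"] / b**2
        + v["endocytosis"] * ((b - a) / b**2) ** 2
        + v["quench_bg"] * (a / b**2) ** 2
    )
    return {"endocytosis_rate": float(se_endo), "recycling_rate": float(se_rec)}


def mfi_ratio(stained: pd.DataFrame, unstained: pd.DataFrame,
              *, channel: str = "fl1") -> float:
    """MFI(stained)/MFI(unstained) — the surface-expression readout (MFI-R)."""
    denom = mfi(unstained, channel)
    if denom <= 0:
        raise ValueError("unstained MFI must be > 0")
    return mfi(stained, channel) / denom


def analyze_panel(events: pd.DataFrame, *, gate: LiveGate | None = None,
                  geometric: bool = False,
                  sign_convention: str = "positive_recycling") -> dict:
    """Gate, normalize and derive rates from a five-group event table.

    Returns a flat report dict with raw/net MFIs, both recycling conventions,
    rates, delta-method standard errors and gate retention; warnings about
    the sign-convention discrepancy and any degenerate nets are in ``flags``.
    """
    panels = {}
    mfis, nev, gvar = {}, {}, {}
    retention = {}
    for group, sub in events.groupby("group"):
        gated = gate_live(sub, gate)
        panels[group] = gated
        mfis[group] = mfi(gated, geometric=geometric)
        nev[group] = len(gated)
        gvar[group] = float(gated["fl1"].var(ddof=1)) if len(gated) > 1 else 0.0
        retention[group] = gated.attrs["retention"]
    panel = normalize_panel(mfis, n_events=nev, group_var=gvar)
    endo = endocytosis_rate(panel)
    rec_pos = recycling_rate(panel, "positive_recycling")
    rec_printed = recycling_rate(panel, "as_printed")
    ses = rate_standard_errors(panel)
    panel.flags.append(
        "recycling sign convention: positive_recycling = -(as_printed); "
        "the as-printed formula is negative for true recycling")
    return {
        "raw_mfi": mfis,
        "net_mfi": panel.net_mfi,
        "endocytosis_rate": endo,
        "recycling_rate": rec_pos,
        "recycling_rate_as_printed": rec_printed,
        "standard_errors": ses,
        "gate_retention": retention,
        "flags": panel.flags,
    }


def timecourse_summary(tables_by_timepoint: dict, *, epsilon: float = 0.1,
                       gate: LiveGate | None = None) -> pd.DataFrame:
    """Per-timepoint endocytosis rates plus a plateau estimate.

    ``tables_by_timepoint`` maps minutes to event tables; control groups
    (unstained, labeled_100, quench_bg) are taken from the earliest table that
    contains them and shared.  The plateau is the earliest timepoint after
    which every successive rate increase is <= epsilon * (max - min) of the
    rate range; the final timepoint never qualifies vacuously, and with < 3
    timepoints no plateau is reported.  The result carries the plateau (or
    None) in ``attrs['plateau_min']``.
    """
    times = sorted(tables_by_timepoint)
    controls: dict = {}
    for t in times:
        tab = tables_by_timepoint[t]
        for g in ("unstained", "labeled_100", "quench_bg"):
            if g not in controls and (tab["group"] == g).any():
                controls[g] = tab[tab["group"] == g]
    missing = [g for g in ("unstained", "labeled_100", "quench_bg")
               if g not in controls]
    if missing:
        raise ValueError(f"no table provides control group(s): {missing}")

    rates = []
    for t in times:
        tab = tables_by_timepoint[t]
        endo = tab[tab["group"] == "endocytosis"]
        if endo.empty:
            raise ValueError(f"timepoint {t}: no endocytosis events")
        mfis = {g: mfi(gate_live(sub, gate)) for g, sub in controls.items()}
        mfis["endocytosis"] = mfi(gate_live(endo, gate))
        mfis["recycling"] = mfis["endocytosis"]  # placeholder; unused for endo
        panel = normalize_panel(mfis)
        rates.append(endocytosis_rate(panel))

    out = pd.DataFrame({"timepoint_min": times, "endocytosis_rate": rates})
    out.attrs["plateau_min"] = _plateau(times, rates, epsilon)
    return out


def _plateau(times, rates, epsilon: float):
    if len(times) < 3:
        warnings.warn("fewer than 3 timepoints: rates only, no plateau",
                      stacklevel=3)
        return None
    rng = max(rates) - min(rates)
    tol = epsilon * rng
    increases = [b - a for a, b in zip(rates, rates[1:])]
    for i in range(len(times) - 1):  # final timepoint excluded (vacuous)
        if all(inc <= tol for inc in increases[i:]):
            return times[i]
    return None
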