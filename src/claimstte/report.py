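"""Rendering of emulation outputs as publication-style tables.

Display conventions: risks and risk differences as percentages to one
decimal, risk ratios to two decimals, NNT/NNH as integers, confidence
intervals as "(lo, hi)".  All rounding is half-up decimal rounding so that
rendered values reproduce standard effect arithmetic (e.g. 1/0.054 -> 19),
and every displayed value derives from a stored full-precision value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 0) -> float:
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(risk: float, ndigits: int = 1) -> str:
    """0.29942 -> '29.9%'"""
    return f"{round_half_up(100.0 * risk, ndigits):.{ndigits}f}%"


def format_ratio(rr: float) -> str:
    """0.9492 -> '0.95'"""
    if not np.isfinite(rr):
        return "undefined"
    return f"{round_half_up(rr, 2):.2f}"


def format_nn(label: str, value: float) -> str:
    if label == "undefined" or not np.isfinite(value):
        return "undefined"
    return f"{label} {int(value)}"


def format_ci(lo: float, hi: float, as_percent: bool = False) -> str:
    if as_percent:
        return f"({round_half_up(100 * lo, 1):.1f}, {round_half_up(100 * hi, 1):.1f})"
    return f"({round_half_up(lo, 2):.2f}, {round_half_up(hi, 2):.2f})"


def parse_percent(text: str) -> float:
    """Inverse of :func:`format_percent` (to rounding tolerance)."""
    return float(text.rstrip("%")) / 100.0


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    rendered: dict[str, pd.DataFrame]
    balance: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def _render_estimates(tab: pd.DataFrame) -> pd.DataFrame:
    out = tab.copy()
    for col in ("risk_treated", "risk_control", "risk_difference"):
        if col in out:
            out[col] = out[col].map(format_percent)
    if "risk_ratio" in out:
        out["risk_ratio"] = out["risk_ratio"].map(format_ratio)
    if "nn_value" in out:
        out["nn"] = [format_nn(l, v) for l, v in zip(out["nn_label"], out["nn_value"])]
        out = out.drop(columns=["nn_label", "nn_value"])
    return out


def format_estimates(tables: dict[str, pd.DataFrame],
                     balance: pd.DataFrame | None = None,
                     manifest: dict | None = None,
                     ci: dict | None = None,
                     truth: dict | None = None) -> ReportBundle:
    rendered = {}
    for name, tab in tables.items():
        if "risk_treated" in tab.columns:
            rendered[name] = _render_estimates(tab)
        else:
            rendered[name] = tab
    return ReportBundle(tables=tables, rendered=rendered, balance=balance,
                        manifest=manifest or {}, ci=ci or {}, truth=truth or {})


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    tdir = out / "report_tables"
    tdir.mkdir(parents=True, exist_ok=True)
    for name, tab in bundle.tables.items():
        tab.to_csv(tdir / f"{name}.csv", index=False)
    for name, tab in bundle.rendered.items():
        tab.to_csv(tdir / f"{name}_rendered.csv", index=False)
    payload = {"manifest": bundle.manifest, "ci": bundle.ci, "truth": bundle.truth}
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=str))
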