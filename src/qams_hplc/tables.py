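"""Loaders for the published reference tables shipped as fixtures.

Three tables anchor the numerical checks: the calibration summary
(linear equations, r, ranges, LOD/LOQ), the multipoint RCF table
(per-injection-volume RCFs with Mean and RSD% rows), and the batch content
comparison (ES vs. QAMS mass percentages with signed RE%).  A sha256
manifest guards against silent fixture edits.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

__all__ = [
    "load_calibration_table",
    "load_rcf_table",
    "load_content_table",
    "load_stock_solutions",
    "ANALYTES",
    "INTERNAL_REFERENCE",
    "BATCHES",
]

#: elution-independent canonical analyte order used across reports.
ANALYTES = ["matrine", "gallic_acid", "oxymatrine", "catechin", "rutin", "ferulic_acid"]
INTERNAL_REFERENCE = "gallic_acid"
BATCHES = ["20171201", "20171202", "20171203", "20171204", "20171205"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("qams_hplc.data")
    manifest = json.loads((ref / "manifest.json").read_text())
    raw = (ref / name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if manifest.get(name) != digest:
        raise ValueError(f"fixture checksum mismatch for {name}")
    with (ref / name).open() as fh:
        return pd.read_csv(fh, dtype={"batch": str, "injection_volume_uL": str})


def load_calibration_table() -> pd.DataFrame:
    """Calibration summary: slope, intercept, r, linear range, LOD, LOQ per analyte."""
    return _read("table2_calibration.csv").set_index("analyte")


def load_rcf_table() -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Multipoint RCF table.

    Returns ``(per_injection, printed_mean, printed_rsd)`` where
    ``per_injection`` is indexed by injection volume (µL) with one column per
    analyte, and the two Series are the table's printed Mean and RSD% rows.
    """
    df = _read("table3_rcf.csv").set_index("injection_volume_uL")
    mean = df.loc["Mean"].astype(float)
    rsd = df.loc["RSD%"].astype(float)
    per_injection = df.drop(index=["Mean", "RSD%"]).astype(float)
    per_injection.index = per_injection.index.astype(int)
    return per_injection, mean, rsd


def load_content_table() -> pd.DataFrame:
    """Batch content comparison, indexed by (batch, method) with method in
    {ES, QAMS, RE}; RE is blank (NaN) for the internal reference."""
    return _read("table4_contents.csv").set_index(["batch", "method"])


def load_stock_solutions() -> pd.DataFrame:
    """Stock standard concentrations, both as printed and under the
    range-consistent relabeling used by the synthetic study defaults (see
    docs/methods.md for why the two disagree)."""
    return _read("stock_solutions.csv").set_index("analyte")
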