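"""Reference EC values for the six Epimedium flavonoid standards.

Assay-derived EC5-EC50 values (μg/mL) from a RAW264.7 osteoclast
growth-inhibition test for the six prenylflavonoid standards used in the
mixture-design workflow: epimedin A, epimedin B, epimedin C, icariin,
baohuoside I and icartin. These feed the uniform-design mixture ratios and
serve as ground truth for Hill-consistency checks.
"""

from __future__ import annotations

from .hill import EC_LEVELS, ECTable

__all__ = ["STANDARD_EC_TABLES", "standard_ec_table"]


def _table(name: str, concs: tuple[float, ...]) -> ECTable:
    return ECTable(name=name, values=dict(zip(EC_LEVELS, concs)))


#: EC5, EC10, EC20, EC30, EC40, EC50 per standard, μg/mL.
STANDARD_EC_TABLES: tuple[ECTable, ...] = (
    _table("epimedin A", (8.11, 41.00, 238.09, 766.50, 1998.72, 4816.47)),
    _table("epimedin B", (7.14, 19.86, 60.32, 126.22, 231.21, 402.92)),
    _table("epimedin C", (0.02, 0.52, 18.53, 199.07, 1394.17, 8318.58)),
    _table("icariin", (0.91, 3.24, 12.80, 31.91, 67.48, 134.17)),
    _table("baohuoside I", (13.77, 21.32, 34.26, 46.95, 60.79, 77.06)),
    _table("icartin", (1.90, 4.73, 12.73, 24.56, 42.09, 69.02)),
)


def standard_ec_table(name: str) -> ECTable:
    """Look up one standard's EC table by (case-insensitive) name."""
    for table in STANDARD_EC_TABLES:
        if table.name.lower() == name.lower():
            return table
    raise KeyError(f"unknown standard: {name!r}")
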