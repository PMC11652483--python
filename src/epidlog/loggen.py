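"""The EPIDLOG/1.0 machine-log text dialect.

An open, versioned stand-in for the binary "dynalog" style formats consumed
by commercial dose-recalculation software (whose ingestible format is
proprietary and unverified here). Layout:

    EPIDLOG/1.0
    # plan_id: <text>
    # beam_energy: <label>
    # n_leaf_pairs: <int>
    # total_mu: <float>
    # <any further key: value headers, preserved verbatim>
    index\ttime_s\tgantry_deg\tcollimator_deg\tcumulative_mu\tA0..An-1\tB0..Bn-1
    <one tab-separated record per frame>

Numeric precision: leaf positions to 0.01 mm, MU to 0.0001, angles to 0.01
degree, time to 1 ms. Parsing and re-serializing a file reproduces it
byte for byte. Axis convention (recorded in the header): cross-plane mm at
the isocenter plane, bank A on the negative side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

MAGIC = "EPIDLOG/1.0"
REQUIRED_HEADERS = ("plan_id", "beam_energy", "n_leaf_pairs", "total_mu")


class LogFormatError(ValueError):
    pass


@dataclass
class LogRecord:
    frame_index: int
    time_s: float
    gantry_deg: float
    collimator_deg: float
    cumulative_mu: float
    bank_a_mm: list[float]
    bank_b_mm: list[float]


@dataclass
class EpidLogFile:
    header: dict[str, str]  # insertion-ordered; values kept as text
    records: list[LogRecord] = field(default_factory=list)

    @property
    def n_leaf_pairs(self) -> int:
        return int(self.header["n_leaf_pairs"])

    @property
    def total_mu(self) -> float:
        return float(self.header["total_mu"])

    def validate(self) -> None:
        for key in REQUIRED_HEADERS:
            if key not in self.header:
                raise LogFormatError(f"missing required header {key!r}")
        n = self.n_leaf_pairs
        prev = -float("inf")
        for rec in self.records:
            if len(rec.bank_a_mm) != n or len(rec.bank_b_mm) != n:
                raise LogFormatError(
                    f"record {rec.frame_index}: bank arrays must have length {n}"
                )
            if rec.cumulative_mu < prev - 1e-9:
                raise LogFormatError(
                    f"record {rec.frame_index}: cumulative MU decreases "
                    f"({rec.cumulative_mu} after {prev})"
                )
            prev = rec.cumulative_mu


def _format_record(rec: LogRecord) -> str:
    cells = [
        str(rec.frame_index),
        f"{rec.time_s:.3f}",
        f"{rec.gantry_deg:.2f}",
        f"{rec.collimator_deg:.2f}",
        f"{rec.cumulative_mu:.4f}",
    ]
    cells += [f"{v:.2f}" for v in rec.bank_a_mm]
    cells += [f"{v:.2f}" for v in rec.bank_b_mm]
    return "\t".join(cells)


def write_epid_log(path, log: EpidLogFile) -> None:
    """Serialize; refuses to write a log violating its invariants."""
    log.validate()
    n = log.n_leaf_pairs
    columns = ["index", "time_s", "gantry_deg", "collimator_deg", "cumulative_mu"]
    columns += [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    lines = [MAGIC]
    lines += [f"# {k}: {v}" for k, v in log.header.items()]
    lines.append("\t".join(columns))
    lines += [_format_record(r) for r in log.records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_epid_log(path) -> EpidLogFile:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != MAGIC:
        raise LogFormatError(f"{path}: not an {MAGIC} file")
    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i].startswith("# "):
        body = lines[i][2:]
        if ": " not in body:
            raise LogFormatError(f"{path}:{i + 1}: malformed header line {lines[i]!r}")
        key, value = body.split(": ", 1)
        header[key] = value
        i += 1
    log = EpidLogFile(header=header)
    log.validate()  # checks required headers before touching records
    n = log.n_leaf_pairs
    if i >= len(lines):
        raise LogFormatError(f"{path}: missing column header line")
    i += 1  # column header
    expected_cells = 5 + 2 * n
    records = []
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != expected_cells:
            raise LogFormatError(
                f"{path}:{lineno}: expected {expected_cells} fields, got {len(cells)}"
            )
        try:
            records.append(
                LogRecord(
                    frame_index=int(cells[0]),
                    time_s=float(cells[1]),
                    gantry_deg=float(cells[2]),
                    collimator_deg=float(cells[3]),
                    cumulative_mu=float(cells[4]),
                    bank_a_mm=[float(v) for v in cells[5 : 5 + n]],
                    bank_b_mm=[float(v) for v in cells[5 + n :]],
                )
            )
        except ValueError as exc:
            raise LogFormatError(f"{path}:{lineno}: {exc}") from exc
    log.records = records
    log.validate()
    return log
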