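"""Plain-text file formats for every pipeline stage, with schema validation.

Formats (all CSV/TSV/FASTA):

* decay: ``time_s,signal`` -- CPMG echo decays
* feeding: ``batch,initial_mg,remaining_mg,feces_mg``
* composition: tidy ``sample,fraction,sugar,amount`` (``sugar="total"`` rows
  carry whole-fraction masses)
* evidence: TSV ``protein_id,peptide,expect,sample,compartment,replicate``
* melt: ``temp_C,fluorescence``
* spectrum: ``ppm,intensity``
* FASTA protein sequences
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .composition import BiomassSample, FeedingRecord
from .proteomics import VALID_RESIDUES
from .relaxometry import CPMGDecay
from .spectra import Spectrum
from .thermal import MeltCurve

__all__ = [
    "read_decay", "write_decay",
    "read_feeding", "write_feeding",
    "read_composition", "write_composition",
    "read_evidence", "write_evidence",
    "read_fasta", "write_fasta",
    "read_melt", "write_melt",
    "read_spectrum", "write_spectrum",
    "validate_file", "ValidationReport",
]


def write_decay(decay: CPMGDecay, path: str | Path) -> None:
    pd.DataFrame({"time_s": decay.time, "signal": decay.signal}).to_csv(path, index=False)


def read_decay(path: str | Path) -> CPMGDecay:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "signal"], path)
    return CPMGDecay(time=df["time_s"].to_numpy(), signal=df["signal"].to_numpy())


def write_feeding(records: list[FeedingRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"batch": r.batch, "initial_mg": r.initial_mg,
             "remaining_mg": r.remaining_mg, "feces_mg": r.feces_mg}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_feeding(path: str | Path) -> list[FeedingRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["batch", "initial_mg", "remaining_mg", "feces_mg"], path)
    return [
        FeedingRecord(
            batch=str(r.batch), initial_mg=r.initial_mg,
            remaining_mg=r.remaining_mg, feces_mg=r.feces_mg,
        )
        for r in df.itertuples()
    ]


def write_composition(samples: list[BiomassSample], path: str | Path) -> None:
    from .synth import composition_table

    composition_table(samples).to_csv(path, index=False)


def read_composition(path: str | Path) -> list[BiomassSample]:
    from .synth import samples_from_table

    df = pd.read_csv(path)
    _require_columns(df, ["sample", "fraction", "sugar", "amount"], path)
    return samples_from_table(df)


def write_evidence(evidence: pd.DataFrame, path: str | Path) -> None:
    evidence.to_csv(path, sep="\t", index=False)


def read_evidence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, ["protein_id", "peptide", "expect", "sample", "compartment", "replicate"], path
    )
    return df


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_melt(curve: MeltCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"temp_C": curve.temperature, "fluorescence": curve.fluorescence}
    ).to_csv(path, index=False)


def read_melt(path: str | Path) -> MeltCurve:
    df = pd.read_csv(path)
    _require_columns(df, ["temp_C", "fluorescence"], path)
    return MeltCurve(
        temperature=df["temp_C"].to_numpy(), fluorescence=df["fluorescence"].to_numpy()
    )


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    _require_columns(df, ["ppm", "intensity"], path)
    return Spectrum(ppm=df["ppm"].to_numpy(), intensity=df["intensity"].to_numpy())


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    path: str
    kind: str
    ok: bool
    issues: list[str]


_KINDS = ("decay", "feeding", "composition", "evidence", "fasta", "melt", "spectrum")


def validate_file(path: str | Path, kind: str) -> ValidationReport:
    """Schema-check one input file; issues name the first offending row."""
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}")
    path = Path(path)
    issues: list[str] = []
    if not path.exists():
        return ValidationReport(str(path), kind, False, ["file does not exist"])
    try:
        checker = globals()[f"_check_{kind}"]
        issues = checker(path)
    except Exception as exc:  # malformed beyond row-level diagnosis
        issues = [f"unreadable as {kind}: {exc}"]
    return ValidationReport(str(path), kind, not issues, issues)


def _first_bad(mask: np.ndarray) -> int:
    return int(np.argmax(mask)) + 2  # +1 header, +1 one-based


def _check_decay(path: Path) -> list[str]:
    df = pd.read_csv(path)
    issues = []
    for col in ("time_s", "signal"):
        if col not in df.columns:
            issues.append(f"missing column {col!r}")
    if issues:
        return issues
    t = df["time_s"].to_numpy()
    if np.any(t <= 0):
        issues.append(f"non-positive time at row {_first_bad(t <= 0)}")
    bad = np.diff(t) <= 0
    if bad.any():
        issues.append(f"non-monotone time at row {_first_bad(bad) + 1}")
    return issues


def _check_feeding(path: Path) -> list[str]:
    df = pd.read_csv(path)
    issues = []
    for col in ("batch", "initial_mg", "remaining_mg", "feces_mg"):
        if col not in df.columns:
            issues.append(f"missing column {col!r}")
    if issues:
        return issues
    neg = (df[["initial_mg", "remaining_mg", "feces_mg"]] < 0).any(axis=1).to_numpy()
    if neg.any():
        issues.append(f"negative mass at row {_first_bad(neg)}")
    over = (df["remaining_mg"] > df["initial_mg"]).to_numpy()
    if over.any():
        issues.append(f"remaining exceeds initial at row {_first_bad(over)}")
    return issues


def _check_composition(path: Path) -> list[str]:
    df = pd.read_csv(path)
    issues = []
    for col in ("sample", "fraction", "sugar", "amount"):
        if col not in df.columns:
            issues.append(f"missing column {col!r}")
    if issues:
        return issues
    neg = (df["amount"] < 0).to_numpy()
    if neg.any():
        issues.append(f"negative amount at row {_first_bad(neg)}")
    return issues


def _check_evidence(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    issues = []
    for col in ("protein_id", "peptide", "expect", "sample", "compartment", "replicate"):
        if col not in df.columns:
            issues.append(f"missing column {col!r}")
    if issues:
        return issues
    bad = (~df["peptide"].astype(str).map(lambda p: set(p) <= VALID_RESIDUES)).to_numpy()
    if bad.any():
        issues.append(f"invalid peptide residues at row {_first_bad(bad)}")
    neg = (df["expect"] < 0).to_numpy()
    if neg.any():
        issues.append(f"negative expect score at row {_first_bad(neg)}")
    return issues


def _check_fasta(path: Path) -> list[str]:
    issues = []
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        bad = set(str(rec.seq).upper()) - VALID_RESIDUES
        if bad:
            issues.append(f"record {rec.id}: illegal residues {sorted(bad)}")
    if n == 0:
        issues.append("no FASTA records found")
    return issues


def _check_melt(path: Path) -> list[str]:
    df = pd.read_csv(path)
    issues = []
    for col in ("temp_C", "fluorescence"):
        if col not in df.columns:
            issues.append(f"missing column {col!r}")
    if issues:
        return issues
    t = df["temp_C"].to_numpy()
    bad = np.diff(t) <= 0
    if bad.any():
        issues.append(f"non-monotone temperature at row {_first_bad(bad) + 1}")
    return issues


def _check_spectrum(path: Path) -> list[str]:
    df = pd.read_csv(path)
    issues = []
    for col in ("ppm", "intensity"):
        if col not in df.columns:
            issues.append(f"missing column {col!r}")
    if issues:
        return issues
    d = np.diff(df["ppm"].to_numpy())
    if not (np.all(d > 0) or np.all(d < 0)):
        issues.append("ppm axis is not strictly monotone")
    return issues
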