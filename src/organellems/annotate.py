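"""Accurate-mass annotation of aligned features.

Theoretical monoisotopic [M+H]+ masses are computed for prohormone-derived
peptides (1-based inclusive residue ranges on the precursor, plus common
post-translational modifications), lipid candidates are matched as
protonated or sodiated adducts at a ppm tolerance (7 ppm default), and
prohormone sequence coverage is the fraction of precursor residues spanned
by the union of detected peptide ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESIDUE_MASS",
    "PTM_DELTA",
    "ADDUCT_MASS",
    "WATER",
    "PROTON",
    "PeptideRecord",
    "peptide_mh",
    "peptide_neutral_mass",
    "ppm_error",
    "match_features",
    "sequence_coverage",
    "read_fasta",
    "read_peptide_csv",
    "read_lipid_csv",
    "build_peptide_records",
]

# Standard monoisotopic residue masses (Da).
RESIDUE_MASS: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER = 18.010565
PROTON = 1.007276

# Monoisotopic mass deltas (Da) of the supported modifications.
# "half-disulfide" is the loss of one hydrogen on a cysteine participating
# in an inter-chain bridge; a closed intra-chain bridge removes two.
PTM_DELTA: dict[str, float] = {
    "amidation": -0.984016,
    "acetylation": +42.010565,
    "pyro-glu-Q": -17.026549,
    "pyro-glu-E": -18.010565,
    "phospho": +79.966331,
    "half-disulfide": -1.007825,
    "disulfide": -2.015650,
}

ADDUCT_MASS: dict[str, float] = {
    "[M+H]+": 1.007276,
    "[M+Na]+": 22.989218,
}


@dataclass
class PeptideRecord:
    """A prohormone-derived peptide with its theoretical [M+H]+ m/z."""

    prohormone_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    ptms: tuple[str, ...]
    theoretical_mh: float

    @property
    def name(self) -> str:
        return f"{self.prohormone_id} [{self.start}-{self.end}]"


def peptide_neutral_mass(sequence: str, ptms: Iterable[str] = ()) -> float:
    """Monoisotopic neutral mass: residue masses + water + PTM deltas."""
    total = WATER
    for res in sequence:
        try:
            total += RESIDUE_MASS[res]
        except KeyError:
            raise ValueError(f"unknown residue {res!r} in sequence") from None
    for ptm in ptms:
        try:
            total += PTM_DELTA[ptm]
        except KeyError:
            raise ValueError(
                f"unknown PTM {ptm!r}; supported: {sorted(PTM_DELTA)}"
            ) from None
    return total


def peptide_mh(sequence: str, ptms: Iterable[str] = ()) -> float:
    """Theoretical monoisotopic [M+H]+ m/z of a peptide with PTMs."""
    return peptide_neutral_mass(sequence, ptms) + PROTON


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical_mz must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def match_features(
    features: Sequence[float],
    candidates: pd.DataFrame,
    tolerance_ppm: float = 7.0,
    adducts: Mapping[str, float] | None = None,
    validated_names: Iterable[str] = (),
) -> pd.DataFrame:
    """Match feature m/z values against a candidate mass table.

    ``candidates`` needs columns ``name`` and either ``neutral_mass`` (each
    adduct in ``adducts`` is considered; default +H and +Na) or ``mz``
    (used as-is, adduct reported as ``given-m/z``).  Every
    (feature, candidate, adduct) pair within the inclusive ppm tolerance is
    reported with its signed ppm error; features with several matches are
    flagged ambiguous, and unmatched features appear once with
    ``matched=False``.  ``validated_names`` marks candidates independently
    confirmed (e.g. by LC-MS/MS) in the ``validated`` column.
    """
    if "neutral_mass" not in candidates.columns and "mz" not in candidates.columns:
        raise ValueError("candidates need a 'neutral_mass' or 'mz' column")
    validated = set(validated_names)
    theo: list[tuple[str, str, float]] = []  # (name, adduct, theoretical m/z)
    if "neutral_mass" in candidates:
        add = dict(ADDUCT_MASS) if adducts is None else dict(adducts)
        for _, row in candidates.iterrows():
            m = float(row["neutral_mass"])
            if m <= 0:
                raise ValueError(f"candidate {row['name']!r} has nonpositive mass")
            for aname, amass in add.items():
                theo.append((str(row["name"]), aname, m + amass))
    else:
        for _, row in candidates.iterrows():
            theo.append((str(row["name"]), "given-m/z", float(row["mz"])))

    rows = []
    for f in np.asarray(features, dtype=float):
        hits = []
        for name, adduct, tmz in theo:
            ppm = ppm_error(f, tmz)
            if abs(ppm) <= tolerance_ppm:
                hits.append((name, adduct, tmz, ppm))
        if not hits:
            rows.append(
                {
                    "feature_mz": f,
                    "candidate": None,
                    "adduct": None,
                    "theoretical_mz": np.nan,
                    "ppm": np.nan,
                    "matched": False,
                    "ambiguous": False,
                    "validated": False,
                }
            )
            continue
        for name, adduct, tmz, ppm in hits:
            rows.append(
                {
                    "feature_mz": f,
                    "candidate": name,
                    "adduct": adduct,
                    "theoretical_mz": tmz,
                    "ppm": ppm,
                    "matched": True,
                    "ambiguous": len(hits) > 1,
                    "validated": name in validated,
                }
            )
    return pd.DataFrame(rows)


def sequence_coverage(protein_length: int, ranges: Sequence[tuple[int, int]]) -> float:
    """Fraction of residues covered by the union of 1-based inclusive ranges."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    covered = np.zeros(protein_length, dtype=bool)
    for start, end in ranges:
        if not (1 <= start <= end <= protein_length):
            raise ValueError(
                f"range [{start}-{end}] outside [1, {protein_length}]"
            )
        covered[start - 1 : end] = True
    return float(covered.sum()) / protein_length


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_peptide_csv(path: str | Path) -> pd.DataFrame:
    """Peptide list CSV: prohormone_id,start,end,ptms (';'-separated)."""
    df = pd.read_csv(path)
    need = {"prohormone_id", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"peptide CSV must have columns {sorted(need)}")
    if "ptms" not in df.columns:
        df["ptms"] = ""
    df["ptms"] = df["ptms"].fillna("")
    return df


def read_lipid_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"name", "neutral_mass"} <= set(df.columns):
        raise ValueError("lipid CSV must have columns: name, neutral_mass")
    return df


def build_peptide_records(
    sequences: Mapping[str, str], peptides: pd.DataFrame
) -> list[PeptideRecord]:
    """Resolve residue ranges against precursor sequences into records."""
    out = []
    for _, row in peptides.iterrows():
        pid = str(row["prohormone_id"])
        if pid not in sequences:
            raise KeyError(f"prohormone {pid!r} not found among the sequences")
        seq = sequences[pid]
        start, end = int(row["start"]), int(row["end"])
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(
                f"{pid} [{start}-{end}] outside the {len(seq)}-residue sequence"
            )
        ptms = tuple(p for p in str(row.get("ptms", "")).split(";") if p)
        sub = seq[start - 1 : end]
        out.append(
            PeptideRecord(
                prohormone_id=pid,
                start=start,
                end=end,
                sequence=sub,
                ptms=ptms,
                theoretical_mh=peptide_mh(sub, ptms),
            )
        )
    return out
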