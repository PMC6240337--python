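"""Sequence-derived biochemical traits of mature peptides.

Net charge at a given pH (Henderson-Hasselbalch over the ionizable groups),
molecular weight (average isotopic residue masses plus one water), and an
approximate molecular volume (sum of published mean residue volumes).  The
toxins studied are ICK (inhibitor cystine knot) peptides whose six cysteines
form three disulfide bridges, so bridged cysteines are excluded from the
acidic sum by default when requested.

Volumes are a sequence-level approximation: they ignore packing and solvent
effects that a structure-based calculation would capture, and outputs are
tagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import BadParameter, BadSequence

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: mean residue volumes (A^3), Zamyatnin-style partial volumes of amino acid
#: residues in solution
RESIDUE_VOLUMES_A3 = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: default number of disulfide-bonded cysteines for ICK peptides (three
#: bridges formed by six cysteines)
ICK_BRIDGED_CYS = 6


@dataclass(frozen=True)
class PKaTable:
    """Ionization constants used by the net-charge calculation.

    Defaults are Lehninger-style free-amino-acid values; peptide calculators
    differ in their tables, so the provenance tag travels with every result.
    """

    lys: float = 10.53
    arg: float = 12.48
    his: float = 6.00
    asp: float = 3.65
    glu: float = 4.25
    cys: float = 8.18
    tyr: float = 10.07
    n_term: float = 9.69
    c_term: float = 2.34
    provenance: str = "lehninger"

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if name != "provenance" and not 0.0 < v < 14.0:
                raise BadParameter(f"pKa {name}={v} outside (0, 14)")


DEFAULT_PKA = PKaTable()


@dataclass
class PeptideRecord:
    """A mature peptide sequence (one-letter, 20 standard residues)."""

    id: str
    sequence: str
    clade: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise BadSequence(f"peptide {self.id!r} has an empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise BadSequence(f"peptide {self.id!r} has non-standard "
                              f"residues {sorted(bad)}")


def _as_record(peptide) -> PeptideRecord:
    if isinstance(peptide, PeptideRecord):
        return peptide
    return PeptideRecord(id="", sequence=str(peptide))


def net_charge(peptide, ph: float = 7.0, table: PKaTable = DEFAULT_PKA,
               bridged_cys: int = 0) -> float:
    """Signed net charge (elementary units) at ``ph``.

    Z = sum over basic groups (N-terminus, K, R, H) of 1/(1+10^(pH-pKa))
    minus the acidic sum (C-terminus, D, E, Y and *free* cysteines) of
    1/(1+10^(pKa-pH)).  ``bridged_cys`` cysteines are in disulfide bridges
    and do not ionize.
    """
    rec = _as_record(peptide)
    seq = rec.sequence
    if bridged_cys < 0 or bridged_cys % 2 or bridged_cys > seq.count("C"):
        raise BadParameter(
            f"bridged_cys={bridged_cys} impossible for {seq.count('C')} "
            "cysteines (must be an even number of paired cysteines)")

    def basic(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def acidic(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pka - ph))

    z = basic(table.n_term) - acidic(table.c_term)
    z += seq.count("K") * basic(table.lys)
    z += seq.count("R") * basic(table.arg)
    z += seq.count("H") * basic(table.his)
    z -= seq.count("D") * acidic(table.asp)
    z -= seq.count("E") * acidic(table.glu)
    z -= seq.count("Y") * acidic(table.tyr)
    z -= (seq.count("C") - bridged_cys) * acidic(table.cys)
    return float(z)


def molecular_weight(peptide) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    rec = _as_record(peptide)
    return float(ProteinAnalysis(rec.sequence).molecular_weight())


def molecular_volume(peptide) -> float:
    """Approximate molecular volume in cubic Angstroms: the sum of mean
    per-residue volumes (additive; no packing correction)."""
    rec = _as_record(peptide)
    return float(sum(RESIDUE_VOLUMES_A3[r] for r in rec.sequence))


def read_fasta(path, clade_from_id=None) -> list[PeptideRecord]:
    """Read mature peptides from FASTA; ``clade_from_id`` optionally maps a
    record id to its clade label."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        clade = clade_from_id(rec.id) if clade_from_id else ""
        records.append(PeptideRecord(rec.id, str(rec.seq), clade=clade))
    if not records:
        raise BadSequence(f"no FASTA records in {path}")
    return records


def properties_table(records: list[PeptideRecord], ph: float = 7.0,
                     table: PKaTable = DEFAULT_PKA,
                     bridged_cys: int = 0) -> pd.DataFrame:
    """Per-peptide property table (the comparative trait inputs).

    ``bridged_cys`` is clipped per sequence to the largest even number of
    cysteines actually present, so one scaffold-wide setting (e.g. 6 for
    ICK) can be applied to a mixed family."""
    rows = []
    for rec in records:
        bc = min(bridged_cys, 2 * (rec.sequence.count("C") // 2))
        rows.append({
            "id": rec.id,
            "length": len(rec.sequence),
            f"net_charge_pH{ph:g}": net_charge(rec, ph, table, bc),
            "mw_da": molecular_weight(rec),
            "volume_a3": molecular_volume(rec),
            "clade": rec.clade,
        })
    df = pd.DataFrame(rows).set_index("id")
    df.attrs["pka_provenance"] = table.provenance
    df.attrs["volume_method"] = "sequence-additive (approximate)"
    return df
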