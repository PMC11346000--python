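"""In-silico protease cleavage scanning and enzyme selection.

Digestive enzymes used for tissue dissociation can destroy the very epitopes
an immunoassay depends on.  This module scans protein sequences with
position-specific cleavage rules (PeptideCutter-style dialects), counts
predicted cleavage sites, checks whether a linear antibody epitope survives a
digest, and assembles the three-criterion enzyme-selection report used to
pick a dissociation enzyme that

1. leaves the anti-Ki67 (MIB-1) epitope intact,
2. nicks the cytokeratin cytoskeleton (antibody accessibility), and
3. cleaves collagen (cell isolation).

Conventions
-----------
Residues are numbered 1-based.  A cleavage *site* is the peptide bond between
residues ``i`` and ``i+1`` and is identified by the index ``i``; the last
residue of a chain can therefore never carry a C-side site.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "MIB1_EPITOPE",
    "ProteinRecord",
    "CleavageRule",
    "CleavageReport",
    "read_fasta",
    "load_rule_catalog",
    "scan_cleavage",
    "count_cleavages",
    "epitope_safe",
    "selection_report",
]

#: The 20 canonical one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Linear epitope of the MIB-1 anti-Ki67 antibody clone (21-mer).
MIB1_EPITOPE = "TPKEKAQALEDLAGFKELFQT"


class FastaParseError(ValueError):
    """Raised when a FASTA record is malformed or contains non-canonical letters."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence.

    The sequence must consist solely of the 20 canonical one-letter codes;
    ambiguity codes (B, Z, X, ...) are rejected because cleavage predicates
    are undefined on them.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS:
                raise FastaParseError(
                    f"record {self.id!r}: non-canonical residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageRule:
    """An enzyme's site-specificity predicate.

    A rule fires either through its simple residue specificity
    (``side``/``residue_set`` with ``context_exceptions`` vetoes) or through
    any of its ``motif_rules``.  Either channel may be empty, but not both.

    Parameters
    ----------
    enzyme_name:
        Display name.
    side:
        ``"C"`` — the site is the bond C-terminal of a matched residue;
        ``"N"`` — the bond N-terminal of a matched residue.
    residue_set:
        Residues the simple specificity matches.
    context_exceptions:
        ``(offset, residues)`` pairs that veto a simple-rule site; offsets are
        relative to the matched residue (``+1`` = the next residue).
    motif_rules:
        Position-specific constraint sets for enzymes (thrombin, prolyl
        endopeptidase) whose specificity spans several subsites.  Each motif
        is a list of constraints ``{"offset": k, "in": [...]}`` or
        ``{"offset": k, "not_in": [...]}`` with offsets relative to P1 (the
        residue N-terminal of the scissile bond): P4..P1 are -3..0 and
        P1', P2' are +1, +2.  An ``in`` constraint fails outside the chain;
        a ``not_in`` constraint passes there.
    notes:
        Free-text caveats carried into reports (e.g. minor activities the
        dialect deliberately omits).
    """

    enzyme_name: str
    side: str = "C"
    residue_set: frozenset = frozenset()
    context_exceptions: tuple = ()
    motif_rules: tuple = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("C", "N"):
            raise ValueError(f"side must be 'C' or 'N', got {self.side!r}")
        if not self.residue_set and not self.motif_rules:
            raise ValueError(
                f"rule {self.enzyme_name!r}: residue_set and motif_rules both empty"
            )

    # -- matching ---------------------------------------------------------

    def _simple_site(self, seq: str, bond: int) -> bool:
        """Does the simple residue specificity fire at bond ``bond|bond+1``?"""
        if not self.residue_set:
            return False
        matched = bond if self.side == "C" else bond + 1  # 1-based residue index
        if seq[matched - 1] not in self.residue_set:
            return False
        for offset, residues in self.context_exceptions:
            p = matched + offset
            if 1 <= p <= len(seq) and seq[p - 1] in residues:
                return False
        return True

    def _motif_site(self, seq: str, bond: int) -> bool:
        """Does any motif rule fire at bond ``bond|bond+1``?  P1 = ``bond``."""
        for motif in self.motif_rules:
            ok = True
            for constraint in motif:
                p = bond + constraint["offset"]
                inside = 1 <= p <= len(seq)
                if "in" in constraint:
                    if not inside or seq[p - 1] not in constraint["in"]:
                        ok = False
                        break
                else:
                    if inside and seq[p - 1] in constraint["not_in"]:
                        ok = False
                        break
            if ok:
                return True
        return False

    def fires_at(self, seq: str, bond: int) -> bool:
        return self._simple_site(seq, bond) or self._motif_site(seq, bond)


@dataclass(frozen=True)
class CleavageReport:
    """Ordered cleavage sites of one enzyme on one protein."""

    protein_id: str
    enzyme_name: str
    site_positions: tuple

    @property
    def site_count(self) -> int:
        return len(self.site_positions)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Whitespace inside sequence lines is stripped and sequences are
    upper-cased before validation, so line wrapping and case never affect a
    scan.  Non-canonical letters raise :class:`FastaParseError` naming the
    record and position.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


# ---------------------------------------------------------------------------
# Rule catalog


def _parse_rule(entry: Mapping) -> CleavageRule:
    exceptions = tuple(
        (int(e["offset"]), frozenset(e["residues"]))
        for e in entry.get("context_exceptions", ())
    )
    motifs = []
    for motif in entry.get("motif_rules", ()):
        constraints = []
        for c in motif:
            out = {"offset": int(c["offset"])}
            if "in" in c:
                out["in"] = frozenset(c["in"])
            else:
                out["not_in"] = frozenset(c["not_in"])
            constraints.append(out)
        motifs.append(tuple(constraints))
    return CleavageRule(
        enzyme_name=entry["enzyme_name"],
        side=entry.get("side", "C"),
        residue_set=frozenset(entry.get("residue_set", ())),
        context_exceptions=exceptions,
        motif_rules=tuple(motifs),
        notes=entry.get("notes", ""),
    )


def load_rule_catalog(path=None) -> dict[str, CleavageRule]:
    """Load an enzyme rule catalog (YAML) into ``{name: CleavageRule}``.

    Without a path, loads the catalog shipped with the package
    (``data/enzyme_rules.yaml``), a versioned, editable set of PeptideCutter
    style dialects calibrated for this assay.
    """
    if path is None:
        ref = importlib.resources.files("ki67flow") / "data" / "enzyme_rules.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    rules = [_parse_rule(entry) for entry in doc["enzymes"]]
    return {r.enzyme_name: r for r in rules}


# ---------------------------------------------------------------------------
# Scanning


def scan_cleavage(protein: ProteinRecord, rule: CleavageRule) -> CleavageReport:
    """Scan a protein for every bond where ``rule`` fires.

    Returns the strictly increasing bond indices ``i`` (site = bond between
    residues ``i`` and ``i+1``), all in ``[1, len-1]``.
    """
    seq = protein.sequence
    if not seq:
        raise ValueError(f"record {protein.id!r}: empty sequence cannot be scanned")
    sites = tuple(
        bond for bond in range(1, len(seq)) if rule.fires_at(seq, bond)
    )
    return CleavageReport(
        protein_id=protein.id, enzyme_name=rule.enzyme_name, site_positions=sites
    )


def count_cleavages(protein: ProteinRecord, rule: CleavageRule) -> int:
    """Number of predicted cleavage sites of ``rule`` on ``protein``."""
    return scan_cleavage(protein, rule).site_count


def epitope_safe(protein: ProteinRecord, epitope: str, rule: CleavageRule) -> bool:
    """Does the enzyme leave every occurrence of ``epitope`` intact?

    The scan runs on the full protein so flanking context is honoured.  A
    site is *inside* an occurrence starting at residue ``s`` when its bond
    lies strictly between the epitope's first and last residue, i.e.
    ``s <= bond <= s + len(epitope) - 2``.  All (possibly overlapping)
    occurrences are checked; any internal cut anywhere returns ``False``.
    """
    epitope = epitope.upper()
    seq = protein.sequence
    occurrences = []
    start = seq.find(epitope)
    while start != -1:
        occurrences.append(start + 1)  # 1-based
        start = seq.find(epitope, start + 1)
    if not occurrences:
        raise ValueError(
            f"epitope {epitope!r} not found in record {protein.id!r}"
        )
    sites = scan_cleavage(protein, rule).site_positions
    for s in occurrences:
        lo, hi = s, s + len(epitope) - 2
        if any(lo <= bond <= hi for bond in sites):
            return False
    return True


# ---------------------------------------------------------------------------
# Selection report


def selection_report(
    enzymes: Iterable[CleavageRule],
    target: ProteinRecord,
    epitope: str,
    ck_panel: Sequence[ProteinRecord],
    collagen_panel: Sequence[ProteinRecord],
) -> pd.DataFrame:
    """Three-criterion enzyme-selection table.

    One row per enzyme with per-protein site counts and the selection
    criteria: (1) the target epitope is intact, (2) at least one cytokeratin
    chain is cleaved, (3) at least one collagen chain is cleaved.
    ``selected`` is the conjunction of all three.
    """
    if not ck_panel or not collagen_panel:
        raise ValueError("cytokeratin and collagen panels must be non-empty")
    rows = []
    for rule in enzymes:
        row = {"enzyme": rule.enzyme_name}
        row[f"sites_{target.id}"] = count_cleavages(target, rule)
        ck_counts = {p.id: count_cleavages(p, rule) for p in ck_panel}
        col_counts = {p.id: count_cleavages(p, rule) for p in collagen_panel}
        for pid, n in {**ck_counts, **col_counts}.items():
            row[f"sites_{pid}"] = n
        row["epitope_intact"] = epitope_safe(target, epitope, rule)
        row["cleaves_cytokeratin"] = any(n > 0 for n in ck_counts.values())
        row["cleaves_collagen"] = any(n > 0 for n in col_counts.values())
        row["selected"] = (
            row["epitope_intact"]
            and row["cleaves_cytokeratin"]
            and row["cleaves_collagen"]
        )
        if rule.notes:
            row["notes"] = rule.notes
        rows.append(row)
    return pd.DataFrame(rows)
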