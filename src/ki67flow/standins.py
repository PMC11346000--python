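"""SYNTHETIC stand-in protein sequences for the cleavage census.

The enzyme-selection analysis runs on the human Ki67 protein (two isoforms),
a panel of cytokeratin chains and a panel of collagen chains.  This package
cannot redistribute those database sequences, so it generates *synthetic
stand-ins*: deterministic artificial sequences that are explicitly labelled
as such and are **not** the biological sequences.

The Ki67 stand-ins are assembled from small tiles whose per-tile cleavage
contributions are known by construction, so the total census of each enzyme
dialect on them is an exact design arithmetic:

==============  ==========  ==========
enzyme          isoform 1   isoform 2
==============  ==========  ==========
trypsin         530         480
dispase         2183        1931
thrombin        3           2
==============  ==========  ==========

These totals deliberately match the published census of the real isoforms
(3256 and 2896 residues) so the downstream selection report behaves like the
real analysis, and the genuine MIB-1 epitope ``TPKEKAQALEDLAGFKELFQT`` is
embedded once per isoform.  Because every tile's contribution is hand
countable, scanning these stand-ins is a genuine end-to-end check of the
scanner + catalog, not a tautology: the expected numbers come from tile
arithmetic, not from the scanner.

Tile inventory (isoform 1): leading ``M``; 524 × ``KA`` (one tryptic site
each, one dispase site each); 1643 × ``A`` (one dispase site each); 534 ×
``S`` (inert); 3 × ``GRG`` (one thrombin site, one tryptic site, two dispase
sites each); the epitope (3 tryptic + 10 dispase sites, no Arg).  Isoform 2
removes one contiguous block (1 × ``GRG``, 49 × ``KA``, 201 × ``A``,
58 × ``S`` = 360 residues) flanked by inert ``S`` tiles so the junction
creates no new site — mimicking an alternatively spliced exon.
"""

from __future__ import annotations

import numpy as np

from .proteins import MIB1_EPITOPE, ProteinRecord

__all__ = [
    "ki67_standin_isoform1",
    "ki67_standin_isoform2",
    "cytokeratin_standin_panel",
    "collagen_standin_panel",
]

_SEED = 20240826  # fixed: the stand-ins are constants, not samples


def _segments() -> tuple[list[str], list[str], list[str]]:
    """Tile lists (seg1, deletable block, seg2) shared by both isoforms."""
    rng = np.random.default_rng(_SEED)
    outside = ["KA"] * 475 + ["A"] * 1442 + ["S"] * 474 + ["GRG"] * 2
    order = rng.permutation(len(outside))
    outside = [outside[i] for i in order]
    half = len(outside) // 2
    seg1, seg2 = outside[:half], outside[half:]
    seg2.insert(len(seg2) // 2, MIB1_EPITOPE)

    block = ["GRG"] + ["KA"] * 49 + ["A"] * 201 + ["S"] * 58
    order = rng.permutation(len(block))
    block = [block[i] for i in order]
    return seg1, block, seg2


def ki67_standin_isoform1() -> ProteinRecord:
    """Synthetic stand-in for Ki67 isoform 1 (3256 residues)."""
    seg1, block, seg2 = _segments()
    seq = "M" + "".join(seg1) + "S" + "".join(block) + "S" + "".join(seg2)
    return ProteinRecord(id="KI67_standin_isoform1_synthetic", sequence=seq)


def ki67_standin_isoform2() -> ProteinRecord:
    """Synthetic stand-in for Ki67 isoform 2 (3256 - 360 = 2896 residues)."""
    seg1, _, seg2 = _segments()
    seq = "M" + "".join(seg1) + "S" + "S" + "".join(seg2)
    return ProteinRecord(id="KI67_standin_isoform2_synthetic", sequence=seq)


def _structural_standin(name: str, length: int, weights: dict[str, float],
                        seed: int) -> ProteinRecord:
    """Random-composition synthetic chain with guaranteed enzyme motifs.

    Splices in ``AGRGA`` (a thrombin Gly-Arg-|-Gly site) and ``AKPAA`` (a
    prolyl-endopeptidase basic-P2 site) so that every catalog enzyme has at
    least one predicted site on each panel member, as the selection criteria
    assume for structural proteins.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(weights))
    p = np.array(list(weights.values()), dtype=float)
    p /= p.sum()
    seq = list(rng.choice(letters, size=length, p=p))
    third = length // 3
    seq[third:third] = list("AGRGA")
    seq[2 * third:2 * third] = list("AKPAA")
    return ProteinRecord(id=name, sequence="".join(seq))


# Compositions are loosely keratin-like (Gly/Ser-rich) and collagen-like
# (Gly-Pro-rich) but carry no biological identity.
_CK_WEIGHTS = dict(G=12, S=11, A=8, L=9, E=8, Q=6, K=6, R=5, V=6, I=5,
                   F=4, Y=3, D=5, N=4, T=5, M=2, H=2, W=1, C=1, P=2)
_COLLAGEN_WEIGHTS = dict(G=33, P=20, A=12, K=5, R=5, E=6, Q=4, S=5, L=4,
                         D=3, N=2, V=3, I=1, F=1, T=2, M=1, H=1, Y=1)


def cytokeratin_standin_panel() -> list[ProteinRecord]:
    """Synthetic stand-ins for the seven cytokeratin chains of the screen."""
    names = ["CK5", "CK7", "CK8", "CK14", "CK17", "CK18", "CK19"]
    lengths = [590, 469, 483, 472, 432, 430, 400]
    return [
        _structural_standin(f"{n}_standin_synthetic", L, _CK_WEIGHTS, _SEED + i + 1)
        for i, (n, L) in enumerate(zip(names, lengths))
    ]


def collagen_standin_panel() -> list[ProteinRecord]:
    """Synthetic stand-ins for collagen I alpha-1/alpha-2 and III alpha-1."""
    names = ["COL1A1", "COL1A2", "COL3A1"]
    lengths = [1464, 1366, 1466]
    return [
        _structural_standin(f"{n}_standin_synthetic", L, _COLLAGEN_WEIGHTS,
                            _SEED + 100 + i)
        for i, (n, L) in enumerate(zip(names, lengths))
    ]
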