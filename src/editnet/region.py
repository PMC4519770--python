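"""Coordinate system of the serotonin-receptor (5-HT2CR) editing region.

A-to-I editing at five closely spaced adenosines (sites A, B, E, C, D in
transcript order, all within a 15-nt window) re-codes three consecutive
codons of the receptor's second intracellular loop.  Because inosine is
read as guanosine, an edited site appears as A->G in cDNA sequencing.
Sites A and B fall in the residue-156 codon, E and C in the residue-158
codon, and D in the residue-160 codon, so the 2**5 = 32 mRNA variants
collapse onto 24 protein isoforms.

:class:`EditingRegion` pins the reference amplicon sequence, the 0-based
site offsets and the codon layout; every variant call and every simulated
read is expressed in its coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
import json

from Bio.Seq import Seq

#: Display order of site letters used in variant names (e.g. "ABCD", "ABD").
SITE_DISPLAY_ORDER = "ABCDE"

#: Transcript (5'->3') order of the five sites.
SITE_TRANSCRIPT_ORDER = ("A", "B", "E", "C", "D")

#: Label of the fully unedited variant.
UNEDITED_LABEL = "NONE"


def variant_label(sites: frozenset[str] | set[str] | str) -> str:
    """Canonical name of an edited-site subset: letters in A,B,C,D,E display
    order, the empty set being ``"NONE"``."""
    subset = set(sites)
    unknown = subset - set(SITE_DISPLAY_ORDER)
    if unknown:
        raise ValueError(f"unknown site labels: {sorted(unknown)}")
    return "".join(s for s in SITE_DISPLAY_ORDER if s in subset) or UNEDITED_LABEL


def parse_variant_label(label: str) -> frozenset[str]:
    """Inverse of :func:`variant_label`."""
    if label == UNEDITED_LABEL:
        return frozenset()
    sites = frozenset(label)
    if variant_label(sites) != label:
        raise ValueError(f"{label!r} is not a canonical variant label")
    return sites


@dataclass(frozen=True)
class EditingRegion:
    """Reference amplicon plus the positions and codon phases of the sites.

    Parameters
    ----------
    reference_sequence
        Sense-strand (mRNA-sense cDNA) sequence of the amplified region.
        The base at every site offset must be ``A``.
    site_offsets
        Mapping site letter -> 0-based offset into ``reference_sequence``,
        strictly increasing in transcript order A < B < E < C < D.
    codon_offsets
        Mapping residue index -> 0-based offset of the codon's first base.
        Consecutive residues occupy consecutive codons.
    """

    reference_sequence: str
    site_offsets: dict[str, int]
    codon_offsets: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.reference_sequence.upper()
        object.__setattr__(self, "reference_sequence", seq)
        offsets = dict(self.site_offsets)
        for label, off in offsets.items():
            if not 0 <= off < len(seq):
                raise ValueError(f"site {label} offset {off} outside reference")
            if seq[off] != "A":
                raise ValueError(
                    f"reference base at site {label} (offset {off}) is "
                    f"{seq[off]!r}, expected 'A'"
                )
        order = [s for s in SITE_TRANSCRIPT_ORDER if s in offsets]
        values = [offsets[s] for s in order]
        if values != sorted(values) or len(set(values)) != len(values):
            raise ValueError("site offsets must strictly increase in transcript order")
        if values and max(values) - min(values) + 1 > 15:
            raise ValueError("all sites must lie within a 15-nt window")

    @property
    def sites(self) -> tuple[str, ...]:
        """Site letters present, in transcript order."""
        return tuple(s for s in SITE_TRANSCRIPT_ORDER if s in self.site_offsets)

    @property
    def n_sites(self) -> int:
        return len(self.site_offsets)

    def sequence_for_variant(self, label: str) -> str:
        """Reference sequence with G substituted at the sites of ``label``."""
        sites = parse_variant_label(label)
        missing = sites - set(self.site_offsets)
        if missing:
            raise ValueError(f"variant {label!r} uses sites absent from region")
        seq = list(self.reference_sequence)
        for s in sites:
            seq[self.site_offsets[s]] = "G"
        return "".join(seq)

    def codon_sites(self, residue: int) -> tuple[str, ...]:
        """Site letters falling within the codon of ``residue``."""
        start = self.codon_offsets[residue]
        return tuple(
            s for s in self.sites if start <= self.site_offsets[s] < start + 3
        )

    def translate_codon(self, residue: int, edited_sites: frozenset[str]) -> str:
        """One-letter amino acid of a residue's codon given edited sites
        (inosine read as guanosine)."""
        start = self.codon_offsets[residue]
        codon = list(self.reference_sequence[start : start + 3])
        for s in self.codon_sites(residue):
            if s in edited_sites:
                codon[self.site_offsets[s] - start] = "G"
        return str(Seq("".join(codon)).translate())

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "reference_sequence": self.reference_sequence,
            "site_offsets": dict(self.site_offsets),
            "codon_offsets": {str(k): v for k, v in self.codon_offsets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EditingRegion":
        return cls(
            reference_sequence=d["reference_sequence"],
            site_offsets={k: int(v) for k, v in d["site_offsets"].items()},
            codon_offsets={int(k): int(v) for k, v in d.get("codon_offsets", {}).items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EditingRegion":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_region() -> EditingRegion:
    """Synthetic five-site editing region used throughout the package.

    The codon layout is the unique one consistent with the receptor's
    editing genetics: the unedited triplet reads Ile156-Asn158-Ile160 (INI),
    editing A+B yields VNI, and both ACD and ABCD yield VSV.  Residue 156 is
    ATA with sites A and B at codon positions 1 and 3; residue 158 is AAT
    with E at position 1 and C at position 2; residue 160 is ATT with D at
    position 1.  The flanking sequence is a synthetic stand-in for the real
    amplicon (whose full sequence is not part of this package); only the
    site/codon geometry matters to the analysis.
    """
    left = "GTCCGTCTTGCAGCGGCT"  # 18 nt
    core = "ATA" "AAT" "ATT"  # residues 156-158-160
    right = "CGTTCGGTGCTGAACCTGC"  # 19 nt
    ref = left + core + right
    base = len(left)
    return EditingRegion(
        reference_sequence=ref,
        site_offsets={
            "A": base + 0,
            "B": base + 2,
            "E": base + 3,
            "C": base + 4,
            "D": base + 6,
        },
        codon_offsets={156: base, 158: base + 3, 160: base + 6},
    )


def enumerate_variants(region: EditingRegion) -> list[str]:
    """All ``2**k`` canonical variant labels of a k-site region.

    Ordered deterministically: by number of edited sites, then
    alphabetically; the unedited variant ("NONE") comes first.
    """
    sites = sorted(region.sites)
    labels = []
    for r in range(len(sites) + 1):
        for combo in combinations(sites, r):
            labels.append(variant_label(frozenset(combo)))
    return labels


def enumerate_isoforms(region: EditingRegion) -> dict[str, str]:
    """Map every variant label to its amino-acid triplet (isoform).

    Translating the 32 variants of the full five-site region yields 24
    distinct isoforms: the A/B and E/C codon sharing makes the map
    many-to-one (e.g. ACD and ABCD both encode VSV).
    """
    if not region.codon_offsets:
        raise ValueError("region has no codon map; cannot translate variants")
    covered = {s for r in region.codon_offsets for s in region.codon_sites(r)}
    missing = set(region.sites) - covered
    if missing:
        raise ValueError(f"codon map does not cover sites: {sorted(missing)}")
    residues = sorted(region.codon_offsets)
    mapping: dict[str, str] = {}
    for label in enumerate_variants(region):
        edited = parse_variant_label(label)
        mapping[label] = "".join(region.translate_codon(r, edited) for r in residues)
    return mapping
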