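"""Restriction-digest assay for Kv1.1 (*Kcna1*) I/V-site editing.

Editing of the Kcna1 transcript destroys an MfeI recognition site
(CAATTG); a constitutive MfeI site sits ~50 bp upstream.  Digestion of the
390-bp RT-PCR amplicon therefore yields three fragments (220, 51, 119 bp)
from unedited templates but only two (220, 170 bp) from edited ones.  The
molar ratio of the edited-diagnostic (~170 bp) to unedited-diagnostic
(~119 bp) fragment estimates the edited fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MFEI_SITE = "CAATTG"
#: MfeI cuts C^AATTG: one base into the recognition sequence.
MFEI_CUT_OFFSET = 1

KCNA1_AMPLICON_LENGTH = 390
#: Diagnostic fragment lengths; the assay's conventional sizes differ from
#: the constructed ones by 1 nt, hence the +/-2 nt matching tolerance.
EDITED_DIAGNOSTIC = 170
UNEDITED_DIAGNOSTIC = 119
DIAGNOSTIC_TOLERANCE = 2


@dataclass(frozen=True)
class Amplicon:
    """A PCR amplicon with annotated recognition-site offsets."""

    sequence: str
    recognition_sequence: str = MFEI_SITE

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def site_offsets(self) -> tuple[int, ...]:
        """0-based start offsets of exact recognition-site matches."""
        site, seq = self.recognition_sequence, self.sequence
        out, pos = [], seq.find(site)
        while pos != -1:
            out.append(pos)
            pos = seq.find(site, pos + 1)
        return tuple(out)


@dataclass
class DigestProfile:
    """Fragment lengths with molar abundances (Bioanalyzer-like profile)."""

    fragments: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        if any(ab < 0 for _, ab in self.fragments):
            raise ValueError("molar abundances must be non-negative")

    @property
    def lengths(self) -> list[int]:
        return [l for l, _ in self.fragments]

    def abundance_near(self, length: int, tolerance: int = DIAGNOSTIC_TOLERANCE) -> float:
        return sum(ab for l, ab in self.fragments if abs(l - length) <= tolerance)

    @classmethod
    def merge(cls, profiles, weights) -> "DigestProfile":
        pooled: dict[int, float] = {}
        for prof, w in zip(profiles, weights):
            for l, ab in prof.fragments:
                pooled[l] = pooled.get(l, 0.0) + w * ab
        return cls(sorted(pooled.items()))

    def to_csv(self, path, unit: str = "molar") -> None:
        pd.DataFrame(self.fragments, columns=["length", "abundance"]).assign(
            unit=unit
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mass_units: bool = False) -> "DigestProfile":
        """Load a (length, abundance) CSV; ``mass_units=True`` converts
        Bioanalyzer mass signal to molarity by dividing by length."""
        df = pd.read_csv(path)
        ab = df["abundance"].astype(float)
        if mass_units:
            ab = ab / df["length"].astype(float)
        return cls(list(zip(df["length"].astype(int), ab)))


def _filler(n: int) -> str:
    """Deterministic filler free of AA dinucleotides (hence of CAATTG)."""
    pat = "ACGT"
    return (pat * (n // 4 + 1))[:n]


def build_kcna1_amplicon(edited: bool) -> Amplicon:
    """Synthetic 390-nt Kcna1 amplicon with the assay's digest geometry.

    The constitutive MfeI site is placed so the cut falls at position 220
    and the editing-site MfeI cut at position 271: the unedited digest gives
    220 + 51 + 119 and the edited digest 220 + 170.  ``edited=True``
    replaces the editing-site adenosine with G, destroying the second site.
    The sequence outside the two sites is synthetic filler (the real
    amplicon sequence is not reproduced here); only the cut arithmetic is
    meaningful.
    """
    const_start = 220 - MFEI_CUT_OFFSET  # cut at 220
    edit_start = 271 - MFEI_CUT_OFFSET  # cut at 271 -> fragments 220/51/119
    seq = (
        _filler(const_start)
        + MFEI_SITE
        + _filler(edit_start - const_start - len(MFEI_SITE))
        + MFEI_SITE
        + _filler(KCNA1_AMPLICON_LENGTH - edit_start - len(MFEI_SITE))
    )
    assert len(seq) == KCNA1_AMPLICON_LENGTH
    if edited:
        # the editing event is the first adenosine of the recognition site
        pos = edit_start + 1
        seq = seq[:pos] + "G" + seq[pos + 1 :]
    return Amplicon(seq)


def digest(
    amplicon: Amplicon,
    recognition_sequence: str = MFEI_SITE,
    cut_offset_within_site: int = MFEI_CUT_OFFSET,
) -> DigestProfile:
    """Cut at every exact recognition-site match; unit molarity per fragment.

    Zero matches return the full-length amplicon as a single fragment.
    """
    if not recognition_sequence:
        raise ValueError("recognition sequence must be non-empty")
    site_amp = Amplicon(amplicon.sequence, recognition_sequence.upper())
    cuts = [off + cut_offset_within_site for off in site_amp.site_offsets]
    bounds = [0] + cuts + [site_amp.length]
    lengths = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return DigestProfile([(l, 1.0) for l in lengths])


def estimate_editing(profile: DigestProfile) -> float:
    """Edited fraction from the diagnostic fragment molarities.

    fraction = M(~170) / (M(~170) + M(~119)), matching fragment lengths
    with a +/-2 nt tolerance.  Raises if neither diagnostic is present.
    """
    m_edit = profile.abundance_near(EDITED_DIAGNOSTIC)
    m_unedit = profile.abundance_near(UNEDITED_DIAGNOSTIC)
    if m_edit == 0 and m_unedit == 0:
        raise ValueError(
            "profile contains neither the ~170 nt (edited) nor the "
            "~119 nt (unedited) diagnostic fragment"
        )
    return m_edit / (m_edit + m_unedit)


def gen_digest_mixture(
    fraction_edited: float,
    n_molecules: int = 1,
    seed: int | None = None,
    molarity_cv: float = 0.0,
) -> DigestProfile:
    """Digest profile of an edited/unedited template mixture.

    Molar abundances are proportional to ``fraction_edited`` (edited-form
    fragments) and its complement; ``molarity_cv`` adds multiplicative
    Gaussian noise per fragment to emulate quantification error.
    """
    if not 0.0 <= fraction_edited <= 1.0:
        raise ValueError("fraction_edited must be within [0, 1]")
    if n_molecules < 0:
        raise ValueError("n_molecules must be non-negative")
    edited_prof = digest(build_kcna1_amplicon(edited=True))
    unedited_prof = digest(build_kcna1_amplicon(edited=False))
    weights = [fraction_edited * n_molecules, (1.0 - fraction_edited) * n_molecules]
    prof = DigestProfile.merge([edited_prof, unedited_prof], weights)
    prof.fragments = [(l, ab) for l, ab in prof.fragments if ab > 0]
    if molarity_cv > 0:
        rng = np.random.default_rng(seed)
        prof.fragments = [
            (l, max(ab * (1.0 + molarity_cv * rng.standard_normal()), 0.0))
            for l, ab in prof.fragments
        ]
    return prof
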