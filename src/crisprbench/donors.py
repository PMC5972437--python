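"""ssODN donor design and in-silico RFLP digestion.

A donor oligo inserts a restriction site (e.g. XbaI ``TCTAGA`` or HindIII
``AAGCTT``) at a chosen inter-base point of the target locus, flanked by
homology arms copied from the reference. Donors are single-stranded and carry
a strand identity: ``NT`` (the oligo is the non-target-strand sequence, i.e.
complementary to the target strand that the guide RNA base-pairs with) or
``T`` (the target-strand sequence). The NT and T designs of the same edit are
exact reverse complements with swapped arm labels.

The recommended asymmetric designs extend one arm from 37 to 77 nt: for
SpCas9, a T-strand donor with the longer arm PAM-*distal*; for the Cpf1
nucleases, an NT-strand donor with the longer arm PAM-*proximal*.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nucleases import (
    NucleaseProfile,
    cas9_cut_site,
    cpf1_cut_sites,
    get_profile,
)
from .sites import TargetSite, revcomp

__all__ = [
    "DonorDesign",
    "RESTRICTION_SITES",
    "insertion_point_between_cuts",
    "design_ssodn",
    "recommended_design",
    "in_silico_digest",
    "UnsupportedNucleaseError",
]

#: common 6-cutter recognition sequences; cut offsets are nt from the site
#: start to the cut on the top strand (XbaI T^CTAGA, HindIII A^AGCTT).
RESTRICTION_SITES: dict[str, tuple[str, int]] = {
    "XbaI": ("TCTAGA", 1),
    "HindIII": ("AAGCTT", 1),
}


class UnsupportedNucleaseError(ValueError):
    """No validated donor recommendation exists for this enzyme."""


@dataclass(frozen=True)
class DonorDesign:
    """An ssODN donor.

    ``arm_5``/``arm_3`` are homology-arm lengths on the emitted oligo's own
    5'->3' orientation; ``insertion_point`` is the inter-base coordinate on
    the forward reference strand; ``strand_identity`` records whether the
    oligo is of the target (T) or non-target (NT) strand sequence;
    ``anchor_nuclease`` names the enzyme the PAM-proximal/distal arm labels
    refer to (empty for manually specified designs).
    """

    locus_id: str
    insert_seq: str
    insertion_point: int
    arm_5: int
    arm_3: int
    strand_identity: str
    oligo_seq: str
    anchor_nuclease: str = ""

    def __post_init__(self) -> None:
        if self.strand_identity not in ("NT", "T"):
            raise ValueError("strand_identity must be 'NT' or 'T'")
        if len(self.oligo_seq) != self.arm_5 + len(self.insert_seq) + self.arm_3:
            raise ValueError("oligo length != arm_5 + insert + arm_3")

    @property
    def total_length(self) -> int:
        return len(self.oligo_seq)


def insertion_point_between_cuts(cas9_site: TargetSite, cpf1_site: TargetSite,
                                 cas9_profile: NucleaseProfile | None = None,
                                 cpf1_profile: NucleaseProfile | None = None) -> int:
    """Inter-base point between the Cas9 blunt cut and the Cpf1 non-target nick.

    Midpoint, rounded toward the Cas9 cut; if the cuts coincide, that
    coordinate. The Cpf1 "cleavage site" is its non-target-strand nick.
    """
    if cas9_site.sequence_id != cpf1_site.sequence_id:
        raise ValueError("sites lie on different sequences")
    if cas9_profile is None:
        cas9_profile = get_profile(_single_cas9(cas9_site))
    if cpf1_profile is None:
        cpf1_profile = get_profile(_single_cpf1(cpf1_site))
    c9 = cas9_cut_site(cas9_site, cas9_profile)
    c12, _ = cpf1_cut_sites(cpf1_site, cpf1_profile)
    if c9 == c12:
        return c9
    mid = (c9 + c12) / 2
    # round the half-integer midpoint toward the Cas9 cut
    import math

    return math.floor(mid) if c9 < c12 else math.ceil(mid)


def _single_cas9(site: TargetSite) -> str:
    for name in ("SpCas9", "SaCas9", "NmCas9"):
        if name in site.pam_assignments:
            return name
    raise ValueError("site carries no Cas9-family PAM assignment")


def _single_cpf1(site: TargetSite) -> str:
    for name in ("AsCpf1", "LbCpf1"):
        if name in site.pam_assignments:
            return name
    raise ValueError("site carries no Cpf1-family PAM assignment")


def design_ssodn(
    reference,
    insertion_point: int,
    insert_seq: str,
    arm_5: int,
    arm_3: int,
    strand_identity: str,
    target_strand: str,
    locus_id: str | None = None,
    anchor_nuclease: str = "",
) -> DonorDesign:
    """Assemble an ssODN donor from the reference.

    Parameters
    ----------
    reference : SeqRecord, ``(id, seq)`` pair, or string — forward strand.
    insertion_point : inter-base coordinate on the forward strand.
    arm_5, arm_3 : homology-arm lengths in nt on the *emitted oligo* (its own
        5' and 3' ends).
    strand_identity : ``"NT"`` or ``"T"``.
    target_strand : which reference strand (``"+"`` or ``"-"``) is the target
        strand, i.e. the strand the guide RNA base-pairs with (the protospacer
        is read on the opposite, non-target strand).
    """
    from .sites import _as_id_seq

    seq_id, ref = _as_id_seq(reference)
    if locus_id is None:
        locus_id = seq_id
    if strand_identity not in ("NT", "T"):
        raise ValueError("strand_identity must be 'NT' or 'T'")
    if target_strand not in ("+", "-"):
        raise ValueError("target_strand must be '+' or '-'")
    if arm_5 < 1 or arm_3 < 1:
        raise ValueError("homology arms must be >= 1 nt")
    insert_seq = insert_seq.upper()

    # Which physical reference strand the oligo is copied from: the target
    # strand for a T donor, its complement for an NT donor.
    oligo_is_forward = (strand_identity == "T") == (target_strand == "+")
    up, down = (arm_5, arm_3) if oligo_is_forward else (arm_3, arm_5)
    lo, hi = insertion_point - up, insertion_point + down
    if lo < 0 or hi > len(ref):
        short = max(-lo, hi - len(ref))
        raise ValueError(
            f"homology arms exceed reference bounds by {short} nt "
            f"(need [{lo}, {hi}) in a {len(ref)}-nt reference)"
        )
    fwd = ref[lo:insertion_point] + insert_seq + ref[insertion_point:hi]
    oligo = fwd if oligo_is_forward else revcomp(fwd)
    return DonorDesign(
        locus_id=locus_id,
        insert_seq=insert_seq if oligo_is_forward else revcomp(insert_seq),
        insertion_point=insertion_point,
        arm_5=arm_5,
        arm_3=arm_3,
        strand_identity=strand_identity,
        oligo_seq=oligo,
        anchor_nuclease=anchor_nuclease,
    )


def recommended_design(
    nuclease: str,
    site: TargetSite,
    insert_seq: str,
    reference,
    arm_short: int = 37,
    arm_long: int = 77,
) -> DonorDesign:
    """The asymmetric donor recommended for this enzyme at this site.

    SpCas9 -> T-strand donor, long arm PAM-distal (default 37/77).
    AsCpf1/LbCpf1 -> NT-strand donor, long arm PAM-proximal.
    SaCas9/NmCas9 -> :class:`UnsupportedNucleaseError` (no validated donor
    recommendation for those enzymes).

    The insert is placed at the enzyme's own cut position (blunt cut for
    SpCas9, non-target-strand nick for Cpf1).
    """
    profile = get_profile(nuclease)
    if nuclease in ("SaCas9", "NmCas9"):
        raise UnsupportedNucleaseError(
            f"no validated ssODN donor recommendation for {nuclease}"
        )
    if nuclease not in site.compatible_nucleases:
        raise ValueError(f"site is not compatible with {nuclease}")
    if profile.is_cas9:
        point = cas9_cut_site(site, profile)
        strand_identity = "T"
        long_side = "distal"
    else:
        point, _ = cpf1_cut_sites(site, profile)
        strand_identity = "NT"
        long_side = "proximal"

    # Genomic side of the insertion point nearest the PAM.
    pam = site.pam_assignments[nuclease]
    pam_right_of_point = (pam.start + pam.end) / 2 > point
    if long_side == "proximal":
        long_right = pam_right_of_point
    else:
        long_right = not pam_right_of_point
    up, down = (arm_short, arm_long) if long_right else (arm_long, arm_short)

    # Map genomic (upstream, downstream) arms onto the emitted oligo's 5'/3'.
    target_strand = "-" if site.strand == "+" else "+"
    oligo_is_forward = (strand_identity == "T") == (target_strand == "+")
    arm_5, arm_3 = (up, down) if oligo_is_forward else (down, up)
    return design_ssodn(
        reference,
        point,
        insert_seq,
        arm_5,
        arm_3,
        strand_identity,
        target_strand,
        anchor_nuclease=nuclease,
    )


def in_silico_digest(
    amplicon: str, recognition_seq: str, cut_offset: int = 1
) -> list[int]:
    """Fragment lengths after cutting at every exact occurrence of the site.

    ``cut_offset`` is the top-strand cut position within the recognition
    sequence (1 for XbaI T^CTAGA and HindIII A^AGCTT). Overlapping
    occurrences each contribute a cut; fragment lengths always sum to the
    amplicon length.
    """
    amplicon = amplicon.upper()
    recognition_seq = recognition_seq.upper()
    if len(recognition_seq) < 4:
        raise ValueError("recognition sequence must be >= 4 nt")
    cuts = []
    pos = amplicon.find(recognition_seq)
    while pos != -1:
        cuts.append(pos + cut_offset)
        pos = amplicon.find(recognition_seq, pos + 1)
    cuts = sorted(set(c for c in cuts if 0 < c < len(amplicon)))
    bounds = [0] + cuts + [len(amplicon)]
    return [b - a for a, b in zip(bounds, bounds[1:])]
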