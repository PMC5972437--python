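"""Nuclease profiles: PAM grammars, seed regions, spacer-length ranges, cut-site models.

Five Cas endonucleases are built in. The Cas9 family (SpCas9, SaCas9, NmCas9)
recognises a PAM 3' of the protospacer and makes a blunt double-strand cut a
fixed number of base pairs 5' of the PAM. The Cpf1/Cas12a family (AsCpf1,
LbCpf1) recognises a T-rich PAM 5' of the protospacer and makes a staggered
cut distal to the PAM, nicking the non-target strand 18 nt 3' of the PAM and
the target strand further out, leaving a 5' overhang.

All coordinates are 0-based, half-open, on the forward strand of the subject
sequence; cut positions are inter-base integers. Minus-strand sites are
handled by mirroring the offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "IUPAC",
    "NucleaseProfile",
    "BluntCut",
    "StaggeredCut",
    "WrongModelError",
    "matches_pam",
    "iupac_to_set",
    "builtin_profiles",
    "get_profile",
    "load_profiles",
    "cas9_cut_site",
    "cpf1_cut_sites",
]

#: IUPAC nucleotide ambiguity codes -> the set of concrete bases each matches.
IUPAC: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class WrongModelError(ValueError):
    """A cut-site model was asked of a profile from the wrong nuclease family."""


def iupac_to_set(code: str) -> frozenset[str]:
    """Concrete bases matched by one IUPAC code.

    A pattern 'N' additionally accepts an 'N' in the subject, so that fully
    ambiguous positions never veto a site; every other pattern code rejects
    subject 'N' (conservative site calling).
    """
    try:
        bases = IUPAC[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None
    if code == "N":
        return bases | {"N"}
    return bases


def matches_pam(sequence_window: str, pattern: str) -> bool:
    """True iff ``sequence_window`` satisfies the IUPAC ``pattern`` base by base.

    The window and pattern must have equal length. Subject bases outside
    {A,C,G,T,N} are rejected; subject 'N' only satisfies pattern 'N'.
    """
    if len(sequence_window) != len(pattern):
        raise ValueError(
            f"window length {len(sequence_window)} != pattern length {len(pattern)}"
        )
    for base, code in zip(sequence_window, pattern):
        if base not in iupac_to_set(code):
            return False
    return True


@dataclass(frozen=True)
class BluntCut:
    """Blunt double-strand cut, ``offset`` bp 5' of the PAM on the protospacer strand."""

    offset: int = 3


@dataclass(frozen=True)
class StaggeredCut:
    """Staggered cut distal to a 5' PAM.

    ``non_target_offset``: nick position on the non-target strand, nt 3' of
    the PAM's last base. ``target_offset``: nick on the target strand, further
    from the PAM, producing a 5' overhang of ``target_offset - non_target_offset`` nt.
    """

    non_target_offset: int = 18
    target_offset: int = 23

    @property
    def overhang(self) -> int:
        return self.target_offset - self.non_target_offset


@dataclass(frozen=True)
class NucleaseProfile:
    """PAM grammar and cut geometry for one Cas endonuclease.

    Parameters
    ----------
    name : enzyme identifier, e.g. ``"SpCas9"``.
    pam_pattern : IUPAC string, read 5'->3' on the protospacer strand.
    pam_side : ``"three_prime"`` (Cas9 family) or ``"five_prime"`` (Cpf1 family),
        relative to the protospacer.
    seed_len : PAM-proximal seed length in nt (7 for all built-ins).
    cut_model : :class:`BluntCut` or :class:`StaggeredCut`.
    optimal_spacer_range : inclusive ``(min, max)`` spacer length in nt with
        robust editing activity.
    """

    name: str
    pam_pattern: str
    pam_side: str
    cut_model: BluntCut | StaggeredCut
    optimal_spacer_range: tuple[int, int]
    seed_len: int = 7

    def __post_init__(self) -> None:
        if self.pam_side not in ("three_prime", "five_prime"):
            raise ValueError(f"invalid pam_side {self.pam_side!r}")
        for code in self.pam_pattern:
            if code not in IUPAC:
                raise ValueError(f"invalid IUPAC code {code!r} in PAM pattern")
        lo, hi = self.optimal_spacer_range
        if lo > hi:
            raise ValueError("optimal_spacer_range min > max")
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")

    @property
    def pam_len(self) -> int:
        return len(self.pam_pattern)

    @property
    def is_cas9(self) -> bool:
        return self.pam_side == "three_prime"

    @property
    def is_cpf1(self) -> bool:
        return self.pam_side == "five_prime"


def _profile_from_dict(name: str, spec: Mapping) -> NucleaseProfile:
    cut = spec["cut_model"]
    if cut["kind"] == "blunt":
        model: BluntCut | StaggeredCut = BluntCut(offset=int(cut.get("offset", 3)))
    elif cut["kind"] == "staggered":
        model = StaggeredCut(
            non_target_offset=int(cut.get("non_target_offset", 18)),
            target_offset=int(cut.get("target_offset", 23)),
        )
    else:
        raise ValueError(f"unknown cut model kind {cut['kind']!r}")
    lo, hi = spec["optimal_spacer_range"]
    return NucleaseProfile(
        name=name,
        pam_pattern=str(spec["pam_pattern"]).upper(),
        pam_side=spec["pam_side"],
        cut_model=model,
        optimal_spacer_range=(int(lo), int(hi)),
        seed_len=int(spec.get("seed_len", 7)),
    )


def load_profiles(source=None) -> dict[str, NucleaseProfile]:
    """Load nuclease profiles from a YAML mapping (enzyme name -> schema).

    With no argument, loads the packaged built-in profile table. ``source``
    may be a path or an open text handle using the same schema, letting users
    register custom enzymes.
    """
    if source is None:
        text = (
            resources.files("crisprbench").joinpath("data/nucleases.yaml").read_text()
        )
    elif hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _profile_from_dict(name, spec) for name, spec in raw.items()}


_BUILTIN: dict[str, NucleaseProfile] | None = None


def builtin_profiles() -> dict[str, NucleaseProfile]:
    """The five built-in profiles (SpCas9, SaCas9, NmCas9, AsCpf1, LbCpf1)."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = load_profiles()
    return dict(_BUILTIN)


def get_profile(name: str) -> NucleaseProfile:
    profiles = builtin_profiles()
    try:
        return profiles[name]
    except KeyError:
        raise KeyError(
            f"unknown nuclease {name!r}; registered: {sorted(profiles)}"
        ) from None


def cas9_cut_site(site, profile: NucleaseProfile) -> int:
    """Inter-base coordinate of a Cas9-family blunt cut.

    The cut lies ``profile.cut_model.offset`` bp (default 3) 5' of the first
    PAM base on the protospacer strand, i.e. inside the spacer next to the
    PAM-proximal end. Strand-aware: mirrored for minus-strand sites.
    """
    if not profile.is_cas9:
        raise WrongModelError(f"{profile.name} is not a Cas9-family (3' PAM) nuclease")
    if not isinstance(profile.cut_model, BluntCut):
        raise WrongModelError(f"{profile.name} does not have a blunt cut model")
    pam = site.pam_assignments[profile.name]
    offset = profile.cut_model.offset
    if site.strand == "+":
        return pam.start - offset
    return pam.end + offset


def cpf1_cut_sites(site, profile: NucleaseProfile) -> tuple[int, int]:
    """Inter-base nick coordinates ``(non_target, target)`` of a Cpf1 staggered cut.

    The non-target-strand nick is ``non_target_offset`` nt (default 18) 3' of
    the PAM's last base; the target-strand nick is ``target_offset`` nt
    (default 23), leaving a 5' overhang. Strand-aware.
    """
    if not profile.is_cpf1:
        raise WrongModelError(f"{profile.name} is not a Cpf1-family (5' PAM) nuclease")
    if not isinstance(profile.cut_model, StaggeredCut):
        raise WrongModelError(f"{profile.name} does not have a staggered cut model")
    pam = site.pam_assignments[profile.name]
    nt_off = profile.cut_model.non_target_offset
    t_off = profile.cut_model.target_offset
    if site.strand == "+":
        return pam.end + nt_off, pam.end + t_off
    return pam.start - nt_off, pam.start - t_off
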