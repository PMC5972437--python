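"""Matched-target-site scanning.

A *matched site* is a protospacer that simultaneously satisfies the PAM
requirements of several nucleases: a Cpf1 TTTN on its 5' flank and a combined
Cas9 motif (NGGRRT, or NGGNGATT, or a plain NNNNGATT for long NmCas9 spacers)
on its 3' flank. Scanning both strands of a subject sequence for these
windows yields loci where different Cas enzymes can be compared on identical
protospacers. A second scanner finds Cas9/Cpf1 site *pairs* whose PAM-proximal
7-nt seed regions overlap as genomic intervals, the paired-seed alternative
used when perfectly matched sites are unavailable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .nucleases import (
    NucleaseProfile,
    builtin_profiles,
    iupac_to_set,
    matches_pam,
)

__all__ = [
    "PamAssignment",
    "TargetSite",
    "COMBOS",
    "scan_matched_sites",
    "scan_sites",
    "find_overlapping_seed_pairs",
    "seed_interval",
    "revcomp",
    "sites_to_bed",
    "sites_to_json",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PamAssignment:
    """One nuclease's PAM at a site: forward-strand interval plus its sequence
    as read 5'->3' on the protospacer strand."""

    start: int
    end: int
    seq: str


@dataclass(frozen=True)
class TargetSite:
    """A protospacer hit with the nucleases whose PAM constraints it satisfies.

    Coordinates are 0-based half-open on the forward strand of the subject;
    ``spacer_seq`` is the protospacer as read on ``strand`` (reverse
    complement of the subject substring for minus-strand sites).
    """

    sequence_id: str
    strand: str
    spacer_start: int
    spacer_end: int
    spacer_seq: str
    pam_assignments: dict[str, PamAssignment]
    compatible_nucleases: frozenset[str]

    @property
    def spacer_len(self) -> int:
        return self.spacer_end - self.spacer_start

    def sort_key(self):
        return (self.sequence_id, self.spacer_start, self.strand, self.spacer_end)


#: combo name -> (3' flank IUPAC pattern, compatible nucleases, spacer length cap)
COMBOS: dict[str, tuple[str, frozenset[str], tuple[int, int] | None]] = {
    "cpf1_sp_sa": ("NGGRRT", frozenset({"SpCas9", "SaCas9", "AsCpf1", "LbCpf1"}), None),
    "cpf1_sp_nm": ("NGGNGATT", frozenset({"SpCas9", "NmCas9", "AsCpf1", "LbCpf1"}), None),
    "cpf1_nm_long": ("NNNNGATT", frozenset({"NmCas9", "AsCpf1", "LbCpf1"}), (24, 25)),
}

_CPF1_PAM = "TTTN"


def _as_id_seq(sequence) -> tuple[str, str]:
    """Accept a Biopython SeqRecord, a (id, seq) pair, or a bare string."""
    if hasattr(sequence, "seq") and hasattr(sequence, "id"):
        return str(sequence.id), str(sequence.seq).upper()
    if isinstance(sequence, tuple) and len(sequence) == 2:
        return str(sequence[0]), str(sequence[1]).upper()
    return "seq", str(sequence).upper()


def iupac_match_starts(seq: str, pattern: str) -> np.ndarray:
    """Boolean array: ``out[i]`` is True iff ``seq[i:i+len(pattern)]`` matches.

    Vectorised per pattern position; subject 'N' only satisfies pattern 'N'.
    """
    n, m = len(seq), len(pattern)
    if n < m:
        return np.zeros(0, dtype=bool)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.ones(n - m + 1, dtype=bool)
    for j, code in enumerate(pattern):
        allowed = np.array([ord(b) for b in iupac_to_set(code)], dtype=np.uint8)
        out &= np.isin(arr[j : j + n - m + 1], allowed)
    return out


def _pam_layout(
    strand: int, i: int, L: int, n: int, flank3: str, compatible: frozenset[str]
) -> tuple[int, int, dict[str, tuple[int, int]]]:
    """Forward-strand spacer interval and per-nuclease PAM intervals for a hit.

    ``i`` indexes the start of the TTTN flank on the scanned strand (forward
    for strand=+1, reverse complement for strand=-1); ``L`` is spacer length.
    """
    # intervals on the scanned strand
    sp = (i + 4, i + 4 + L)
    pams = {"AsCpf1": (i, i + 4), "LbCpf1": (i, i + 4)}
    flank_start = i + 4 + L
    if "SpCas9" in compatible:
        pams["SpCas9"] = (flank_start, flank_start + 3)
    if "SaCas9" in compatible:
        pams["SaCas9"] = (flank_start, flank_start + 6)
    if "NmCas9" in compatible:
        pams["NmCas9"] = (flank_start, flank_start + 8)
    if strand == 1:
        return sp[0], sp[1], pams
    mirror = lambda iv: (n - iv[1], n - iv[0])
    return *mirror(sp), {name: mirror(iv) for name, iv in pams.items()}


def scan_matched_sites(
    sequence,
    combo: str,
    spacer_len_range: tuple[int, int] = (17, 25),
) -> list[TargetSite]:
    """Scan both strands for matched sites of the given combo.

    Parameters
    ----------
    sequence : SeqRecord, ``(id, seq)`` pair, or string (uppercase ACGTN).
    combo : one of ``cpf1_sp_sa`` (TTTN...NGGRRT), ``cpf1_sp_nm``
        (TTTN...NGGNGATT), ``cpf1_nm_long`` (TTTN + 24-25 nt spacer +
        NNNNGATT).
    spacer_len_range : inclusive spacer-length window, within 17-25.

    Returns sites sorted by (sequence_id, start, strand), deduplicated by
    (start, end, strand). Windows whose spacer or any PAM contains an
    ambiguous base are not reported.
    """
    if combo not in COMBOS:
        raise ValueError(f"unknown combo {combo!r}; choose from {sorted(COMBOS)}")
    lo, hi = spacer_len_range
    if lo < 17 or hi > 25 or lo > hi:
        raise ValueError("spacer_len_range must lie within [17, 25]")
    flank3, compatible, cap = COMBOS[combo]
    if cap is not None:
        lo, hi = max(lo, cap[0]), min(hi, cap[1])
        if lo > hi:
            return []
    seq_id, seq = _as_id_seq(sequence)
    n = len(seq)
    min_window = 4 + lo + len(flank3)
    if n < min_window or set(seq) - set("ACGTN"):
        logger.warning(
            "sequence %s is empty, too short, or not ACGTN; returning no sites", seq_id
        )
        return []

    hits: dict[tuple[int, int, str], TargetSite] = {}
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        m5 = iupac_match_starts(s, _CPF1_PAM)
        m3 = iupac_match_starts(s, flank3)
        for L in range(lo, hi + 1):
            span = 4 + L + len(flank3)
            if n < span:
                continue
            valid = m5[: n - span + 1] & m3[4 + L : 4 + L + (n - span + 1)]
            for i in np.flatnonzero(valid):
                i = int(i)
                window = s[i : i + span]
                if "N" in window:
                    continue
                start, end, pam_ivs = _pam_layout(strand, i, L, n, flank3, compatible)
                strand_sym = "+" if strand == 1 else "-"
                key = (start, end, strand_sym)
                if key in hits:
                    continue
                spacer_seq = s[i + 4 : i + 4 + L]
                pams = {}
                for name, (a, b) in pam_ivs.items():
                    pam_seq = seq[a:b] if strand == 1 else revcomp(seq[a:b])
                    pams[name] = PamAssignment(a, b, pam_seq)
                hits[key] = TargetSite(
                    sequence_id=seq_id,
                    strand=strand_sym,
                    spacer_start=start,
                    spacer_end=end,
                    spacer_seq=spacer_seq,
                    pam_assignments=pams,
                    compatible_nucleases=compatible,
                )
    return sorted(hits.values(), key=TargetSite.sort_key)


def scan_sites(
    sequence,
    profile: NucleaseProfile,
    spacer_len: int = 20,
) -> list[TargetSite]:
    """Scan both strands for single-nuclease sites (spacer + adjacent PAM)."""
    seq_id, seq = _as_id_seq(sequence)
    n = len(seq)
    pat = profile.pam_pattern
    span = spacer_len + len(pat)
    if n < span:
        return []
    out: dict[tuple[int, int, str], TargetSite] = {}
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        mask = iupac_match_starts(s, pat)
        for j in np.flatnonzero(mask):
            j = int(j)
            if profile.is_cas9:
                sp = (j - spacer_len, j)
            else:
                sp = (j + len(pat), j + len(pat) + spacer_len)
            if sp[0] < 0 or sp[1] > n:
                continue
            window = s[min(sp[0], j) : max(sp[1], j + len(pat))]
            if "N" in window:
                continue
            if strand == 1:
                start, end = sp
                pam_iv = (j, j + len(pat))
            else:
                start, end = n - sp[1], n - sp[0]
                pam_iv = (n - j - len(pat), n - j)
            strand_sym = "+" if strand == 1 else "-"
            key = (start, end, strand_sym)
            if key in out:
                continue
            spacer_seq = s[sp[0] : sp[1]]
            pam_seq = s[j : j + len(pat)]
            out[key] = TargetSite(
                sequence_id=seq_id,
                strand=strand_sym,
                spacer_start=start,
                spacer_end=end,
                spacer_seq=spacer_seq,
                pam_assignments={profile.name: PamAssignment(*pam_iv, pam_seq)},
                compatible_nucleases=frozenset({profile.name}),
            )
    return sorted(out.values(), key=TargetSite.sort_key)


def seed_interval(site: TargetSite, profile: NucleaseProfile) -> tuple[int, int]:
    """Forward-strand interval of the PAM-proximal seed (``profile.seed_len`` nt).

    For a 3'-PAM (Cas9) site the seed is the spacer end adjacent to the PAM;
    for a 5'-PAM (Cpf1) site it is the spacer start adjacent to the PAM —
    both mirrored on minus-strand sites.
    """
    k = profile.seed_len
    pam_at_right = (profile.is_cas9) == (site.strand == "+")
    if pam_at_right:
        return site.spacer_end - k, site.spacer_end
    return site.spacer_start, site.spacer_start + k


def find_overlapping_seed_pairs(
    sequence,
    cas9_profile: NucleaseProfile,
    cpf1_profile: NucleaseProfile,
    seed_len: int | None = None,
    spacer_len: int = 20,
    min_overlap: int = 1,
) -> list[tuple[TargetSite, TargetSite, tuple[int, int]]]:
    """Cas9/Cpf1 site pairs whose PAM-proximal seeds intersect as genomic intervals.

    ``seed_len`` overrides both profiles' seed length when given. The seed
    depends only on the PAM position, so sites are scanned at a single
    representative ``spacer_len``. Returns ``(cas9_site, cpf1_site,
    overlap_interval)`` triples with overlap >= ``min_overlap``.
    """
    if seed_len is not None:
        if seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        from dataclasses import replace

        cas9_profile = replace(cas9_profile, seed_len=seed_len)
        cpf1_profile = replace(cpf1_profile, seed_len=seed_len)
    if not cas9_profile.is_cas9 or not cpf1_profile.is_cpf1:
        raise ValueError("profiles must be (Cas9-family, Cpf1-family) in that order")
    cas9_sites = scan_sites(sequence, cas9_profile, spacer_len)
    cpf1_sites = scan_sites(sequence, cpf1_profile, spacer_len)
    pairs = []
    for a in cas9_sites:
        sa = seed_interval(a, cas9_profile)
        for b in cpf1_sites:
            sb = seed_interval(b, cpf1_profile)
            lo, hi = max(sa[0], sb[0]), min(sa[1], sb[1])
            if hi - lo >= min_overlap:
                pairs.append((a, b, (lo, hi)))
    pairs.sort(key=lambda t: (t[0].sort_key(), t[1].sort_key()))
    return pairs


def sites_to_bed(sites: Iterable[TargetSite]) -> str:
    """BED6 text (name = combo spacer, score = spacer length)."""
    lines = []
    for s in sites:
        lines.append(
            "\t".join(
                [
                    s.sequence_id,
                    str(s.spacer_start),
                    str(s.spacer_end),
                    s.spacer_seq,
                    str(s.spacer_len),
                    s.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def sites_to_json(sites: Iterable[TargetSite]) -> str:
    """JSON sidecar with per-site PAM assignments and compatible nucleases."""
    records = []
    for s in sites:
        records.append(
            {
                "sequence_id": s.sequence_id,
                "strand": s.strand,
                "spacer_start": s.spacer_start,
                "spacer_end": s.spacer_end,
                "spacer_seq": s.spacer_seq,
                "compatible_nucleases": sorted(s.compatible_nucleases),
                "pams": {
                    name: {"start": p.start, "end": p.end, "seq": p.seq}
                    for name, p in sorted(s.pam_assignments.items())
                },
            }
        )
    return json.dumps(records, indent=2)
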