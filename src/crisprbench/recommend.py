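"""Design-guideline rule engine: which Cas system and donor to use.

A deterministic encoding of the benchmark's decision flowchart. The branch
logic, with the supporting observation behind each rule:

* Routine knockout (NHEJ): SpCas9 or LbCpf1 — they generated indels at
  comparable frequencies at optimal spacer lengths, in both lowly and highly
  expressed genes.
* Knockout where specificity is critical (repetitive regions, close
  paralogs): AsCpf1 first (lowest tolerance of single spacer-target
  mismatches), or SaCas9 with spacers of at least 21 nt.
* Precise edit with an ssODN donor: SpCas9 with the 37/77 target-strand (T)
  asymmetric donor, or LbCpf1 with a non-target-strand (NT) donor whose
  PAM-proximal arm is extended (37/77).
* Precise edit with a linearized plasmid donor: SpCas9 performs favorably
  against the Cpf1 enzymes.

Unknown goal/donor combinations fall back to the routine-knockout default
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = ["Recommendation", "recommend_system", "DONOR_ADVICE"]

#: per-enzyme asymmetric ssODN parameters (arm lengths in nt).
DONOR_ADVICE: dict[str, dict] = {
    "SpCas9": {
        "strand_identity": "T",
        "arm_pam_proximal": 37,
        "arm_pam_distal": 77,
        "note": "extend the PAM-distal arm of the target-strand donor (37/77 T)",
    },
    "LbCpf1": {
        "strand_identity": "NT",
        "arm_pam_proximal": 77,
        "arm_pam_distal": 37,
        "note": "extend the PAM-proximal arm of the non-target-strand donor",
    },
}

_RATIONALE = {
    "knockout_default": (
        "SpCas9 and LbCpf1 generate indels at comparable frequencies at optimal "
        "spacer lengths, in both lowly and highly expressed genes"
    ),
    "specificity_ascpf1": (
        "AsCpf1 shows the lowest tolerance of single mismatches between spacer "
        "and target DNA"
    ),
    "specificity_sacas9": (
        "SaCas9 requires longer spacers (at least 21 nt) for activity, reducing "
        "off-target potential"
    ),
    "ssodn_spcas9": (
        "SpCas9 prefers ssODN donors of the target-strand sequence; the 37/77 T "
        "asymmetric donor with a longer PAM-distal arm is optimal"
    ),
    "ssodn_lbcpf1": (
        "the Cpf1 nucleases prefer non-target-strand ssODNs and gain HDR "
        "efficiency from a longer PAM-proximal arm"
    ),
    "plasmid_spcas9": (
        "with linearized plasmid donors SpCas9 performs favorably compared to "
        "the Cpf1 enzymes"
    ),
}


@dataclass(frozen=True)
class Recommendation:
    goal: str
    specificity_critical: bool
    donor: str
    nucleases: tuple[str, ...]
    donor_advice: dict = field(default_factory=dict)
    rationale: tuple[str, ...] = ()
    constraints: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("every recommendation must carry a rationale anchor")


def recommend_system(
    goal: str, specificity_critical: bool = False, donor: str = "none"
) -> Recommendation:
    """Recommend Cas system(s) and donor parameters for an editing goal.

    Parameters
    ----------
    goal : ``"knockout"`` or ``"precise_edit"``.
    specificity_critical : restrict to low-mismatch-tolerance enzymes.
    donor : ``"none"``, ``"ssODN"``, or ``"plasmid"``.
    """
    if goal not in ("knockout", "precise_edit"):
        raise ValueError("goal must be 'knockout' or 'precise_edit'")
    if donor not in ("none", "ssODN", "plasmid"):
        raise ValueError("donor must be 'none', 'ssODN', or 'plasmid'")

    if goal == "knockout":
        if specificity_critical:
            return Recommendation(
                goal, specificity_critical, donor,
                nucleases=("AsCpf1", "SaCas9"),
                rationale=(
                    _RATIONALE["specificity_ascpf1"],
                    _RATIONALE["specificity_sacas9"],
                ),
                constraints={"SaCas9": {"min_spacer_len": 21}},
            )
        return Recommendation(
            goal, specificity_critical, donor,
            nucleases=("SpCas9", "LbCpf1"),
            rationale=(_RATIONALE["knockout_default"],),
        )

    if donor == "ssODN":
        return Recommendation(
            goal, specificity_critical, donor,
            nucleases=("SpCas9", "LbCpf1"),
            donor_advice={k: dict(v) for k, v in DONOR_ADVICE.items()},
            rationale=(_RATIONALE["ssodn_spcas9"], _RATIONALE["ssodn_lbcpf1"]),
        )
    if donor == "plasmid":
        return Recommendation(
            goal, specificity_critical, donor,
            nucleases=("SpCas9",),
            rationale=(_RATIONALE["plasmid_spcas9"],),
        )
    # precise edit without a donor template is not a supported branch
    warnings.warn(
        "precise_edit without a donor has no dedicated guideline; "
        "falling back to knockout defaults",
        stacklevel=2,
    )
    fallback = recommend_system("knockout", specificity_critical, donor="none")
    return Recommendation(
        goal, specificity_critical, donor,
        nucleases=fallback.nucleases,
        rationale=fallback.rationale,
        constraints=fallback.constraints,
    )
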