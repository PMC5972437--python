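"""ssODN assembly identities, strand symmetry, and in-silico digestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprbench import (
    design_ssodn,
    get_profile,
    in_silico_digest,
    insertion_point_between_cuts,
    recommended_design,
    scan_matched_sites,
)
from crisprbench.donors import UnsupportedNucleaseError
from crisprbench.sites import revcomp
from conftest import random_dna

XBAI = "TCTAGA"


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(7)
    return random_dna(rng, 400)


class TestInsertionPoint:
    def test_midpoint_between_cuts(self, matched_site_seq):
        site = scan_matched_sites(("s", matched_site_seq), "cpf1_sp_sa")[0]
        point = insertion_point_between_cuts(site, site)
        from crisprbench import cas9_cut_site, cpf1_cut_sites

        c9 = cas9_cut_site(site, get_profile("SpCas9"))
        c12, _ = cpf1_cut_sites(site, get_profile("LbCpf1"))
        assert min(c9, c12) <= point <= max(c9, c12)

    def test_explicit_midpoint_arithmetic(self):
        # cuts 27 and 35 -> 31; rounding is toward the Cas9 cut for odd gaps
        from crisprbench.donors import insertion_point_between_cuts as ip
        from crisprbench.nucleases import get_profile
        from crisprbench.sites import PamAssignment, TargetSite

        def fake_site(pam_name, start, end):
            return TargetSite(
                "s", "+", 0, 40, "A" * 40,
                {pam_name: PamAssignment(start, end, "NNN")},
                frozenset({pam_name}),
            )

        cas9 = fake_site("SpCas9", 30, 33)  # blunt cut at 27
        cpf1 = fake_site("LbCpf1", 13, 17)  # non-target nick at 35
        assert ip(cas9, cpf1) == 31

    def test_different_sequences_rejected(self, matched_site_seq):
        import dataclasses

        site = scan_matched_sites(("s", matched_site_seq), "cpf1_sp_sa")[0]
        other = dataclasses.replace(site, sequence_id="other")
        with pytest.raises(ValueError):
            insertion_point_between_cuts(site, other)


class TestDesign:
    @pytest.mark.parametrize(
        "arm5,arm3,expected_len",
        [(47, 47, 100), (17, 17, 40), (37, 77, 120), (77, 37, 120)],
    )
    def test_length_identities(self, reference, arm5, arm3, expected_len):
        d = design_ssodn(reference, 200, XBAI, arm5, arm3, "NT", "-")
        assert d.total_length == expected_len

    def test_nt_is_revcomp_of_t(self, reference):
        nt = design_ssodn(reference, 200, XBAI, 30, 50, "NT", "-")
        t = design_ssodn(reference, 200, XBAI, 50, 30, "T", "-")
        assert nt.oligo_seq == revcomp(t.oligo_seq)
        assert (nt.arm_5, nt.arm_3) == (t.arm_3, t.arm_5)

    def test_bounds_error_names_shortfall(self, reference):
        with pytest.raises(ValueError, match="exceed reference bounds"):
            design_ssodn(reference, 10, XBAI, 47, 47, "NT", "-")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        arm5=st.integers(10, 100),
        arm3=st.integers(10, 100),
        strand=st.sampled_from(["NT", "T"]),
        target=st.sampled_from(["+", "-"]),
    )
    def test_length_and_homology_fidelity(self, reference, arm5, arm3, strand, target):
        """total == arm_5 + insert + arm_3; stripping the insert recovers an
        exact substring of the strand-appropriate reference."""
        d = design_ssodn(reference, 200, XBAI, arm5, arm3, strand, target)
        assert d.total_length == arm5 + len(XBAI) + arm3
        assert d.oligo_seq[arm5 : arm5 + len(XBAI)] == d.insert_seq
        stripped = d.oligo_seq[:arm5] + d.oligo_seq[arm5 + len(XBAI) :]
        assert stripped in reference or stripped in revcomp(reference)


@pytest.fixture(scope="module")
def locus():
    rng = np.random.default_rng(5)
    spacer = random_dna(rng, 20)
    seq = random_dna(rng, 150) + "TTTA" + spacer + "AGGAAT" + random_dna(rng, 150)
    sites = [
        s
        for s in scan_matched_sites(("locus", seq), "cpf1_sp_sa")
        if s.spacer_len == 20 and s.strand == "+"
    ]
    assert sites
    return seq, sites[0]


class TestRecommended:

    def test_spcas9_gets_37_77_t_donor(self, locus):
        seq, site = locus
        d = recommended_design("SpCas9", site, XBAI, seq)
        assert d.strand_identity == "T"
        assert {d.arm_5, d.arm_3} == {37, 77}
        assert d.total_length == 120
        assert d.anchor_nuclease == "SpCas9"

    def test_lbcpf1_gets_nt_donor_long_proximal_arm(self, locus):
        seq, site = locus
        d = recommended_design("LbCpf1", site, XBAI, seq)
        assert d.strand_identity == "NT"
        assert {d.arm_5, d.arm_3} == {37, 77}
        # + site, NT donor is the forward strand here (target strand is -),
        # and the Cpf1 PAM lies 5' (left) of the nick: the long PAM-proximal
        # arm must be the oligo's 5' arm
        assert d.arm_5 == 77

    def test_arm_orientation_spcas9(self, locus):
        seq, site = locus
        d = recommended_design("SpCas9", site, XBAI, seq)
        # + site, T donor is the reverse strand; the Cas9 PAM lies 3' (right)
        # of the cut, so PAM-distal (left/upstream) is long; after revcomp the
        # genomic upstream arm becomes the oligo's 3' arm
        assert d.arm_3 == 77

    @pytest.mark.parametrize("enzyme", ["SaCas9", "NmCas9"])
    def test_unsupported_enzymes_raise(self, locus, enzyme):
        seq, site = locus
        with pytest.raises(UnsupportedNucleaseError):
            recommended_design(enzyme, site, XBAI, seq)


class TestDigest:
    def test_single_cut(self):
        amp = "A" * 40 + XBAI + "C" * 54
        frags = in_silico_digest(amp, XBAI)
        assert len(frags) == 2
        assert sum(frags) == 100

    def test_no_site_full_length(self):
        assert in_silico_digest("ACGT" * 25, XBAI) == [100]

    def test_k_sites_give_k_plus_1_fragments(self, rng):
        for k in (1, 2, 3, 5):
            parts = [random_dna(rng, 20).replace("TCTAGA", "TCTACA") for _ in range(k + 1)]
            amp = XBAI.join(parts)
            frags = in_silico_digest(amp, XBAI)
            assert len(frags) == k + 1
            assert sum(frags) == len(amp)
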