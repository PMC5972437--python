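"""Synthetic amplicon loci and reads with ground-truth editing outcomes.

The generator builds a random locus carrying exactly one embedded matched
target site, derives the donor edit (a XbaI site inserted between the Cas9
blunt cut and the Cpf1 non-target nick), and then simulates amplicon reads as
a programmed mixture of four molecule categories:

* ``wt`` — the unedited reference;
* ``indel`` — the reference carrying one NHEJ-like indel whose span
  intersects the spacer, placed near the Cas9 cut (cut +/- 5 nt, mimicking
  repair locality); lengths are geometric, truncated at 25 nt;
* ``hdr_correct`` — the donor-modified reference (restriction site inserted);
* ``hdr_wrong`` — the modified reference with an additional indel inside the
  classification window but clear of the inserted site.

Substitution sequencing errors are applied uniformly per base (no simulated
sequencing indels, so truth labels stay unambiguous at error rate 0). All
randomness flows from a single mandatory integer seed through
``numpy.random.default_rng``, making outputs byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import AmpliconExperiment
from .donors import DonorDesign, design_ssodn, insertion_point_between_cuts
from .nucleases import cas9_cut_site, get_profile
from .sites import TargetSite, scan_matched_sites

__all__ = [
    "SimConfig",
    "SimTruth",
    "LocusFixture",
    "make_locus_fixture",
    "simulate_reads",
    "write_fastq",
    "write_fasta",
    "truth_to_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: HDR-scheme label implied by each simulated molecule category.
EXPECTED_HDR_LABEL = {
    "wt": "No",
    "indel": "No",
    "hdr_correct": "Correct",
    "hdr_wrong": "Wrong",
}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``fractions`` are the (wt, indel, hdr_correct, hdr_wrong) molecule
    proportions; realized per-category counts are one multinomial draw.
    ``indel_geom_p`` parameterises the geometric indel-length distribution
    (mean 1/p), truncated at ``max_indel_len``; ``ins_fraction`` splits
    indels into insertions vs deletions. ``sub_rate`` is the per-base
    substitution sequencing-error probability. ``seed`` is mandatory.
    """

    seed: int
    ref_len: int = 240
    combo: str = "cpf1_sp_sa"
    spacer_len: int = 20
    n_reads: int = 10_000
    fractions: tuple[float, float, float, float] = (0.6, 0.3, 0.07, 0.03)
    indel_geom_p: float = 0.3
    max_indel_len: int = 25
    ins_fraction: float = 0.5
    sub_rate: float = 0.001
    read_len: int | None = None
    flank: int = 40
    insert_seq: str = "TCTAGA"  # XbaI
    arm_len: int = 47

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, float)
        if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be >= 0 and sum to 1")
        if not (0.0 <= self.sub_rate <= 0.05):
            raise ValueError("sub_rate must lie in [0, 0.05]")
        if not (0.0 < self.indel_geom_p <= 1.0):
            raise ValueError("indel_geom_p must lie in (0, 1]")
        min_len = self.spacer_len + 12 + 2 * self.flank
        if self.ref_len < min_len:
            raise ValueError(
                f"ref_len {self.ref_len} too small to embed a site with "
                f"{self.flank}-bp flanks (need >= {min_len})"
            )


@dataclass
class LocusFixture:
    """A synthetic locus: reference, its single matched site, donor, experiment."""

    reference: SeqRecord
    site: TargetSite
    donor: DonorDesign
    experiment: AmpliconExperiment

    @property
    def reference_seq(self) -> str:
        return str(self.reference.seq)


@dataclass
class SimTruth:
    """Ground truth for one simulated read set.

    ``categories[i]`` is read i's molecule category; ``nhej_ops[i]`` is the
    simulated indel operation ('I'/'D', or '' for indel-free categories) and
    ``nhej_lens[i]`` its length. ``counts`` are realized per-category totals.
    """

    categories: list[str]
    nhej_ops: list[str]
    nhej_lens: list[int]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {
                cat: self.categories.count(cat)
                for cat in ("wt", "indel", "hdr_correct", "hdr_wrong")
            }

    @property
    def n_reads(self) -> int:
        return len(self.categories)

    def expected_hdr_labels(self) -> list[str]:
        return [EXPECTED_HDR_LABEL[c] for c in self.categories]

    def expected_nhej_labels_plain_ref(self) -> list[str]:
        """NHEJ labels implied when classifying wt/indel molecules against the
        unmodified reference (undefined for the HDR categories, returned as '')."""
        out = []
        for cat, op in zip(self.categories, self.nhej_ops):
            if cat == "wt":
                out.append("Match")
            elif cat == "indel":
                out.append("Insertion" if op == "I" else "Deletion")
            else:
                out.append("")
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _instantiate_iupac(rng: np.random.Generator, pattern: str) -> str:
    from .nucleases import IUPAC

    return "".join(rng.choice(sorted(IUPAC[c])) for c in pattern)


def make_locus_fixture(config: SimConfig) -> LocusFixture:
    """Build a random reference with exactly one embedded matched site.

    The site (TTTN + spacer + combined 3' PAM) is placed mid-sequence on the
    forward strand; backgrounds that create extra matched sites, destroy the
    embedded one, or already contain the recognition sequence are resampled.
    Deterministic under ``config.seed``.
    """
    from .sites import COMBOS

    rng = np.random.default_rng([config.seed, 0])
    flank3, compatible, _cap = COMBOS[config.combo]
    for _attempt in range(200):
        cassette = (
            "TTT"
            + _instantiate_iupac(rng, "N")
            + _random_seq(rng, config.spacer_len)
            + _instantiate_iupac(rng, flank3)
        )
        start = (config.ref_len - len(cassette)) // 2
        ref = (
            _random_seq(rng, start)
            + cassette
            + _random_seq(rng, config.ref_len - start - len(cassette))
        )
        sites = scan_matched_sites(("locus", ref), config.combo)
        if len(sites) != 1 or config.insert_seq in ref:
            continue
        site = sites[0]
        cas9_name = next(
            n for n in ("SpCas9", "SaCas9", "NmCas9") if n in site.compatible_nucleases
        )
        point = insertion_point_between_cuts(
            site, site, get_profile(cas9_name), get_profile("LbCpf1")
        )
        donor = design_ssodn(
            ("locus", ref),
            point,
            config.insert_seq,
            config.arm_len,
            config.arm_len,
            strand_identity="NT",
            target_strand="-" if site.strand == "+" else "+",
            anchor_nuclease=cas9_name,
        )
        experiment = AmpliconExperiment(
            reference_seq=ref,
            spacer_start=site.spacer_start,
            spacer_end=site.spacer_end,
            flank=config.flank,
            insert_seq=config.insert_seq,
            insertion_point=point,
            recognition_seq=config.insert_seq,
        )
        if config.insert_seq not in experiment.modified_reference_seq:
            continue  # insertion context must leave the site intact
        record = SeqRecord(Seq(ref), id="locus", description="synthetic amplicon")
        return LocusFixture(record, site, donor, experiment)
    raise RuntimeError("could not embed a unique matched site; increase ref_len")


def _sample_indel_len(rng: np.random.Generator, config: SimConfig) -> int:
    return int(min(rng.geometric(config.indel_geom_p), config.max_indel_len))


def _apply_indel(
    rng: np.random.Generator,
    template: str,
    op: str,
    length: int,
    region: tuple[int, int],
    forbid: tuple[int, int] | None = None,
) -> str | None:
    """Apply one indel anchored in ``region``; deletions must stay inside the
    template and clear of ``forbid``. Candidates that could left-shift under
    leftmost gap normalisation (last indel base equals the base before the
    event) are rejected so the event stays at its sampled position and truth
    labels remain exact. Returns None when no placement fits."""
    lo, hi = region
    for _ in range(50):
        if op == "I":
            pos = int(rng.integers(lo, hi + 1))
            if forbid and forbid[0] < pos < forbid[1]:
                continue
            ins = _random_seq(rng, length)
            if pos > 0 and ins[-1] == template[pos - 1]:
                continue
            return template[:pos] + ins + template[pos:]
        anchor = int(rng.integers(lo, hi + 1))
        start = max(1, anchor - length // 2)
        end = start + length
        if end >= len(template):
            continue
        if forbid and start < forbid[1] and end > forbid[0]:
            continue
        if end <= lo or start >= hi:
            continue
        if template[start - 1] == template[end - 1]:
            continue
        return template[:start] + template[end:]
    return None


def _apply_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_reads(
    fixture: LocusFixture, config: SimConfig
) -> tuple[list[SeqRecord], SimTruth]:
    """Simulate amplicon reads from the programmed outcome mixture.

    Returns FASTQ-ready SeqRecords (constant Q30 qualities) in shuffled order
    and the aligned :class:`SimTruth`. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    exp = fixture.experiment
    ref = exp.reference_seq
    mod = exp.modified_reference_seq
    cas9_name = fixture.donor.anchor_nuclease or "SpCas9"
    cut = cas9_cut_site(fixture.site, get_profile(cas9_name))
    sp_s, sp_e = exp.spacer_start, exp.spacer_end

    # indel anchor region: Cas9 cut +/- 5 nt, intersected with the spacer
    region = (max(sp_s, cut - 5), min(sp_e, cut + 5))
    # hdr_wrong indels: inside the (modified-reference) window, clear of the insert
    win = exp.window
    ins_iv = (exp.insertion_point, exp.insertion_point + len(exp.insert_seq))
    wrong_region = (max(1, win[0]), min(len(mod) - 1, win[1]))

    counts = rng.multinomial(config.n_reads, config.fractions)
    order = ["wt", "indel", "hdr_correct", "hdr_wrong"]
    cats: list[str] = []
    ops: list[str] = []
    lens: list[int] = []
    seqs: list[str] = []
    for cat, k in zip(order, counts):
        for _ in range(int(k)):
            op, length = "", 0
            if cat == "wt":
                tpl = ref
            elif cat == "hdr_correct":
                tpl = mod
            else:
                # the simulated indel must not create (indel category) or
                # duplicate/destroy (hdr_wrong) the recognition sequence,
                # so truth labels stay exact at zero sequencing error
                want = 0 if cat == "indel" else 1
                tpl = None
                for _ in range(50):
                    op = "I" if rng.random() < config.ins_fraction else "D"
                    length = _sample_indel_len(rng, config)
                    if cat == "indel":
                        cand = _apply_indel(rng, ref, op, length, region)
                    else:
                        cand = _apply_indel(
                            rng, mod, op, length, wrong_region, forbid=ins_iv
                        )
                    if cand is not None and cand.count(config.insert_seq) == want:
                        tpl = cand
                        break
                if tpl is None:  # fall back to a 1-nt deletion at the anchor
                    op, length = "D", 1
                    base = ref if cat == "indel" else mod
                    pos = region[0] if cat == "indel" else wrong_region[0]
                    tpl = base[:pos] + base[pos + 1 :]
            cats.append(cat)
            ops.append(op)
            lens.append(length)
            seqs.append(tpl)

    perm = rng.permutation(len(seqs))
    cats = [cats[i] for i in perm]
    ops = [ops[i] for i in perm]
    lens = [lens[i] for i in perm]
    seqs = [seqs[i] for i in perm]

    records = []
    for i, s in enumerate(seqs):
        s = _apply_substitutions(rng, s, config.sub_rate)
        if config.read_len is not None:
            s = s[: config.read_len]
        rec = SeqRecord(Seq(s), id=f"read_{i:06d}", description="")
        rec.letter_annotations["phred_quality"] = [30] * len(s)
        records.append(rec)
    truth = SimTruth(categories=cats, nhej_ops=ops, nhej_lens=lens)
    return records, truth


def write_fastq(records: Sequence[SeqRecord], path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, path, "fastq")


def write_fasta(records: Sequence[SeqRecord], path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, path, "fasta")


def truth_to_tsv(truth: SimTruth) -> str:
    lines = ["read_id\tcategory\tindel_op\tindel_len"]
    for i, (c, o, l) in enumerate(
        zip(truth.categories, truth.nhej_ops, truth.nhej_lens)
    ):
        lines.append(f"read_{i:06d}\t{c}\t{o or '.'}\t{l}")
    return "\n".join(lines) + "\n"
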