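"""Synthetic data generators: haplotype mixtures and multi-tissue cohorts.

Two experiments are emulated.  First, the mixture-dilution validation: two
full-length haplotypes differing at a fixed number of sites (default 27) are
mixed at a known minor fraction and sequenced to high coverage; per-position,
per-strand base counts are drawn with Poisson depth around the target coverage
(default 17,500 per strand, i.e. ~35,000 total), binomial sampling of the
minor haplotype at the differing sites, and a uniform per-base miscall rate.
Second, a multi-tissue tumor cohort: patients carry low-level germline
heteroplasmies (some below the 1% detection limit), tumors acquire somatic
mutations that may be shared with recurrences and lymph-node metastases at
clonally expanded levels, and recurrent strand-biased artifact positions are
injected across samples.  Ground-truth labels are emitted for every variant.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .caller import CallThreshold, HeteroplasmyCall, call_site, write_calls
from .errors import DesignError
from .pileup import BASE_INDEX, BASES, Pileup, StrandBaseCounts
from .reference import GENOME_LENGTH, MitoGenome

DEFAULT_COVERAGE_PER_STRAND = 17_500  # ~35,000x total, the study's coverage
DEFAULT_ERROR_RATE = 5e-4  # typical post-Q30 Illumina substitution miscalls


def synthetic_genome(seed: int = 0, length: int = GENOME_LENGTH,
                     gc: float = 0.44) -> MitoGenome:
    """A synthetic stand-in for the rCRS: a random circular sequence with
    mtDNA-like GC content.  Used wherever tests need a full-length genome
    without bundling the real reference."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list(BASES), size=length, p=probs))
    return MitoGenome(sequence=seq, name=f"synthetic-{seed}")


@dataclass
class MixtureDesign:
    """Two haplotypes mixed at a known minor fraction."""

    haplotype_a: str
    haplotype_b: str
    differing_sites: list[int]
    fraction_b: float = 0.01
    coverage_per_strand: float = DEFAULT_COVERAGE_PER_STRAND
    error_rate: float = DEFAULT_ERROR_RATE
    copy_number_skew: float = 1.0  # relative mtDNA copies per unit total DNA
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.haplotype_a) != len(self.haplotype_b):
            raise DesignError("haplotypes must have equal length")
        for pos in self.differing_sites:
            if self.haplotype_a[pos - 1] == self.haplotype_b[pos - 1]:
                raise DesignError(f"haplotypes agree at listed site {pos}")
        if not 0.0 <= self.fraction_b <= 0.5:
            raise DesignError("fraction_b is the minor component, must be <= 0.5")
        if not 0.0 <= self.error_rate < 0.1:
            raise DesignError("error_rate must be a small probability")

    @property
    def effective_fraction_b(self) -> float:
        """Minor fraction of mtDNA molecules after copy-number skew."""
        fb = self.fraction_b * self.copy_number_skew
        return fb / (fb + (1.0 - self.fraction_b))


def make_haplotype_pair(
    genome: MitoGenome | str,
    n_diff: int = 27,
    seed: int = 0,
    fraction_b: float = 0.01,
    coverage_per_strand: float = DEFAULT_COVERAGE_PER_STRAND,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> MixtureDesign:
    """Mixture design with two haplotypes differing at ``n_diff`` uniformly
    placed substitution sites (haplotype A is the reference)."""
    seq_a = genome.sequence if isinstance(genome, MitoGenome) else str(genome)
    if n_diff < 0 or n_diff > len(seq_a):
        raise DesignError(f"n_diff={n_diff} impossible for length {len(seq_a)}")
    rng = np.random.default_rng(seed)
    sites = sorted(rng.choice(len(seq_a), size=n_diff, replace=False) + 1) \
        if n_diff else []
    seq_b = list(seq_a)
    for pos in sites:
        ref = seq_a[pos - 1]
        alts = [b for b in BASES if b != ref]
        seq_b[pos - 1] = alts[rng.integers(len(alts))]
    return MixtureDesign(
        haplotype_a=seq_a,
        haplotype_b="".join(seq_b),
        differing_sites=[int(p) for p in sites],
        fraction_b=fraction_b,
        coverage_per_strand=coverage_per_strand,
        error_rate=error_rate,
        seed=seed,
    )


def _scatter_miscalls(counts: np.ndarray, error_rate: float,
                      rng: np.random.Generator) -> None:
    """Reassign each counted base to a uniformly chosen other base with
    probability ``error_rate`` (in place)."""
    if error_rate <= 0:
        return
    for src in range(4):
        m = rng.binomial(counts[..., src], error_rate)
        counts[..., src] -= m
        others = [b for b in range(4) if b != src]
        x1 = rng.binomial(m, 1.0 / 3.0)
        x2 = rng.binomial(m - x1, 0.5)
        counts[..., others[0]] += x1
        counts[..., others[1]] += x2
        counts[..., others[2]] += m - x1 - x2


def simulate_mixture_counts(design: MixtureDesign) -> Pileup:
    """Strand-resolved base counts for a sequenced haplotype mixture.

    Depth per position per strand is Poisson around ``coverage_per_strand``
    (50/50 strand split); at differing sites the minor-haplotype base count is
    Binomial(depth, fraction); miscalls are scattered uniformly at
    ``error_rate`` everywhere.  The pileup reference is haplotype A.
    """
    rng = np.random.default_rng(design.seed)
    L = len(design.haplotype_a)
    a_idx = np.array([BASE_INDEX[b] for b in design.haplotype_a])
    depths = rng.poisson(design.coverage_per_strand, size=(L, 2))
    counts = np.zeros((L, 2, 4), dtype=np.int64)
    counts[np.arange(L)[:, None], [0, 1], a_idx[:, None]] = depths
    fb = design.effective_fraction_b
    for pos in design.differing_sites:
        i = pos - 1
        bi = BASE_INDEX[design.haplotype_b[i]]
        for s in (0, 1):
            k = rng.binomial(depths[i, s], fb)
            counts[i, s, a_idx[i]] -= k
            counts[i, s, bi] += k
    _scatter_miscalls(counts, design.error_rate, rng)
    return Pileup(design.haplotype_a, counts)


def mixture_recovery(
    design: MixtureDesign,
    pileup: Pileup | None = None,
    threshold: CallThreshold = CallThreshold(0.008),
) -> dict:
    """Run the dual-strand caller on a simulated mixture and summarise how
    well the known minor fraction is recovered at the differing sites."""
    if pileup is None:
        pileup = simulate_mixture_counts(design)
    estimates = []
    detected = 0
    for pos in design.differing_sites:
        site = pileup.site(pos)
        result = call_site(site, threshold)
        if isinstance(result, HeteroplasmyCall):
            detected += 1
            estimates.append(result.level_pct)
    return {
        "n_sites": len(design.differing_sites),
        "detected": detected,
        "mean_minor_pct": float(np.mean(estimates)) if estimates else float("nan"),
        "estimates": estimates,
    }


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Study conditions for a synthetic multi-tissue tumor cohort.

    Defaults emulate the cohort structure of the oral-cancer study this
    pipeline targets: 28 patients, blood in ~4/28, recurrences in ~6/28 and
    lymph-node metastases in ~5/28; roughly three low-level germline
    heteroplasmies per patient dominated by minor components below 10%; tumors
    acquiring a few somatic mutations, most of them shared with later lesions
    at clonally expanded levels (expansion factors around 1.4-4.2); and two
    recurrent low-level strand-biased artifact positions.
    """

    n_patients: int = 28
    blood_fraction: float = 4 / 28
    recurrence_fraction: float = 6 / 28
    metastasis_fraction: float = 5 / 28
    germline_het_rate: float = 3.0  # Poisson mean per patient
    germline_level_log_mu: float = np.log(3.5)
    germline_level_log_sigma: float = 0.9
    germline_level_min: float = 0.3  # below 1% = undetected in the germline
    germline_level_max: float = 60.0
    tumor_presence_prob: float = 0.9  # germline variant also seen in tumor
    germline_drift_sigma: float = 0.6  # lognormal drift of tumor-side levels
    somatic_rate: float = 3.0  # Poisson mean somatic mutations per tumor
    somatic_level_log_mu: float = np.log(10.0)
    somatic_level_log_sigma: float = 0.9
    somatic_level_min: float = 1.5
    somatic_level_max: float = 95.0
    shared_somatic_prob: float = 0.7  # somatic mutation carried into relapse
    expansion_log_mu: float = np.log(2.5)
    expansion_log_sigma: float = 0.4
    artifact_positions: tuple[int, ...] = (72, 414)
    artifact_prob: float = 0.4  # per-sample injection probability
    artifact_level_range: tuple[float, float] = (1.0, 2.0)
    strand_drop_ratio: float = 0.52  # forward-coverage drop at artifact sites
    coverage_per_strand: float = DEFAULT_COVERAGE_PER_STRAND
    n_homoplasmic_germline: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.blood_fraction, self.recurrence_fraction,
                  self.metastasis_fraction, self.tumor_presence_prob,
                  self.shared_somatic_prob, self.artifact_prob):
            if not 0.0 <= p <= 1.0:
                raise DesignError(f"probability {p} outside [0, 1]")
        if np.exp(self.expansion_log_mu) < 1.0:
            raise DesignError(
                "expansion multiplier below 1 contradicts the required "
                "benign->tumor level increase"
            )


@dataclass
class TruthVariant:
    patient_id: str
    position: int
    status: str  # germline_homoplasmic | germline_heteroplasmy | somatic_shared | somatic_private | artifact
    true_levels: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortSimulation:
    sample_sheet: pd.DataFrame
    calls_by_sample: dict[str, list[HeteroplasmyCall]]
    truth: list[TruthVariant]
    genome: MitoGenome
    homoplasmies_by_sample: dict[str, list[int]] = field(default_factory=dict)


def _trunc_lognormal(rng, mu, sigma, lo, hi) -> float:
    for _ in range(1000):
        v = float(rng.lognormal(mu, sigma))
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def _measured_call(rng, genome: MitoGenome, position: int, alt: str,
                   level_pct: float, coverage: float, sample: str,
                   fwd_depth_factor: float = 1.0) -> HeteroplasmyCall | None:
    """Binomial measurement of a true level followed by the dual-strand rule.

    Returns the call the pipeline would make at ~this coverage, or None when
    the variant stays below the 1% dual-strand threshold.
    """
    ref = genome.base(position)
    df = int(rng.poisson(coverage * fwd_depth_factor))
    dr = int(rng.poisson(coverage))
    if df == 0 or dr == 0:
        return None
    f = level_pct / 100.0
    kf = int(rng.binomial(df, f))
    kr = int(rng.binomial(dr, f))
    counts = StrandBaseCounts(
        position=position, ref_base=ref,
        counts_forward={b: 0 for b in BASES} | {ref: df - kf, alt: kf},
        counts_reverse={b: 0 for b in BASES} | {ref: dr - kr, alt: kr},
    )
    result = call_site(counts, CallThreshold(0.01), sample=sample)
    return result if isinstance(result, HeteroplasmyCall) else None


def simulate_cohort(design: CohortDesign,
                    genome: MitoGenome | None = None) -> CohortSimulation:
    """Simulate a multi-tissue cohort with ground-truth variant labels.

    Emits a sample sheet, per-sample heteroplasmy call sets (measurement noise
    and the 1% dual-strand detection rule applied), per-sample homoplasmic
    germline variant positions, and truth records whose status reflects the
    realised placement (a somatic mutation becomes ``somatic_shared`` only if
    it was actually placed in two or more cancerous tissues).
    """
    rng = np.random.default_rng(design.seed)
    genome = genome or synthetic_genome(seed=design.seed)
    used_positions: set[int] = set(design.artifact_positions)

    def fresh_position() -> int:
        while True:
            pos = int(rng.integers(1, GENOME_LENGTH + 1))
            if pos not in used_positions:
                used_positions.add(pos)
                return pos

    def alt_base(position: int) -> str:
        ref = genome.base(position)
        alts = [b for b in BASES if b != ref]
        return alts[int(rng.integers(3))]

    sheet_rows = []
    calls: dict[str, list[HeteroplasmyCall]] = {}
    homoplasmies: dict[str, list[int]] = {}
    truth: list[TruthVariant] = []

    for pi in range(design.n_patients):
        patient = f"P{pi + 1:02d}"
        tissues = ["benign_margin", "primary_tumor"]
        if rng.random() < design.blood_fraction:
            tissues.append("blood")
        if rng.random() < design.recurrence_fraction:
            tissues.append("recurrence")
        if rng.random() < design.metastasis_fraction:
            tissues.append("lymph_node_metastasis")
        sample_ids = {}
        for cls in tissues:
            sid = f"{patient}_{cls}"
            sample_ids[cls] = sid
            sheet_rows.append({"patient_id": patient, "sample_id": sid,
                               "tissue_class": cls})
            calls[sid] = []
            homoplasmies[sid] = []

        benign_side = [c for c in tissues if c in ("benign_margin", "blood")]
        cancer_side = [c for c in tissues
                       if c in ("primary_tumor", "recurrence",
                                "lymph_node_metastasis")]

        # homoplasmic germline variants: present in every sample
        for _ in range(design.n_homoplasmic_germline):
            pos = fresh_position()
            for sid in sample_ids.values():
                homoplasmies[sid].append(pos)
            truth.append(TruthVariant(patient, pos, "germline_homoplasmic"))

        # low-level germline heteroplasmies, possibly drifting in the tumor
        for _ in range(rng.poisson(design.germline_het_rate)):
            pos = fresh_position()
            alt = alt_base(pos)
            base_level = _trunc_lognormal(
                rng, design.germline_level_log_mu,
                design.germline_level_log_sigma,
                design.germline_level_min, design.germline_level_max,
            )
            true_levels = {}
            for cls in benign_side:
                true_levels[cls] = base_level
            for cls in cancer_side:
                if rng.random() < design.tumor_presence_prob:
                    drift = float(rng.lognormal(0.0, design.germline_drift_sigma))
                    true_levels[cls] = float(
                        np.clip(base_level * drift, 0.0, 99.0)
                    )
            truth.append(TruthVariant(patient, pos, "germline_heteroplasmy",
                                      true_levels))
            for cls, level in true_levels.items():
                call = _measured_call(rng, genome, pos, alt, level,
                                      design.coverage_per_strand,
                                      sample_ids[cls])
                if call is not None:
                    calls[sample_ids[cls]].append(call)

        # somatic mutations arising in the primary tumor
        later = [c for c in cancer_side if c != "primary_tumor"]
        for _ in range(rng.poisson(design.somatic_rate)):
            pos = fresh_position()
            alt = alt_base(pos)
            level = _trunc_lognormal(
                rng, design.somatic_level_log_mu, design.somatic_level_log_sigma,
                design.somatic_level_min, design.somatic_level_max,
            )
            true_levels = {"primary_tumor": level}
            for cls in later:
                if rng.random() < design.shared_somatic_prob:
                    mult = float(rng.lognormal(design.expansion_log_mu,
                                               design.expansion_log_sigma))
                    true_levels[cls] = float(np.clip(level * mult, 1.0, 97.0))
            status = "somatic_shared" if len(true_levels) >= 2 else "somatic_private"
            truth.append(TruthVariant(patient, pos, status, true_levels))
            for cls, lvl in true_levels.items():
                call = _measured_call(rng, genome, pos, alt, lvl,
                                      design.coverage_per_strand,
                                      sample_ids[cls])
                if call is not None:
                    calls[sample_ids[cls]].append(call)

    # recurrent strand-biased artifact positions across the whole cohort
    lo, hi = design.artifact_level_range
    for pos in design.artifact_positions:
        affected = []
        for row in sheet_rows:
            sid = row["sample_id"]
            if rng.random() < design.artifact_prob:
                level = float(rng.uniform(lo, hi))
                call = _measured_call(
                    rng, genome, pos, alt_base(pos), level,
                    design.coverage_per_strand, sid,
                    fwd_depth_factor=design.strand_drop_ratio,
                )
                if call is not None:
                    calls[sid].append(call)
                    affected.append(sid)
        truth.append(TruthVariant("cohort", pos, "artifact",
                                  {"samples": len(affected)}))

    for sid in calls:
        calls[sid].sort(key=lambda c: c.position)
    sample_sheet = pd.DataFrame(sheet_rows,
                                columns=["patient_id", "sample_id", "tissue_class"])
    return CohortSimulation(
        sample_sheet=sample_sheet,
        calls_by_sample=calls,
        truth=truth,
        genome=genome,
        homoplasmies_by_sample=homoplasmies,
    )


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture(outputs: dict, directory) -> dict[str, str]:
    """Write generated objects as plain-text files; byte-stable under a fixed
    seed.  Recognised keys: ``genome`` / ``haplotypes`` (FASTA), ``pileup``
    (TSV), ``calls_by_sample`` (one TSV per sample), ``sample_sheet`` (TSV)
    and ``truth`` (JSON).  Returns a name -> sha256 manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def fasta(path: Path, entries: list[tuple[str, str]]) -> None:
        with open(path, "w") as out:
            for name, seq in entries:
                out.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    out.write(seq[i:i + 70] + "\n")
        written.append(path)

    if "genome" in outputs:
        g = outputs["genome"]
        fasta(directory / "genome.fasta", [(g.name, g.sequence)])
    if "haplotypes" in outputs:
        d = outputs["haplotypes"]
        fasta(directory / "haplotypes.fasta",
              [("haplotype_a", d.haplotype_a), ("haplotype_b", d.haplotype_b)])
    if "pileup" in outputs:
        path = directory / "pileup.tsv"
        outputs["pileup"].to_tsv(path)
        written.append(path)
    if "calls_by_sample" in outputs:
        for sid in sorted(outputs["calls_by_sample"]):
            path = directory / f"calls_{sid}.tsv"
            write_calls(outputs["calls_by_sample"][sid], path)
            written.append(path)
    if "sample_sheet" in outputs:
        path = directory / "samples.tsv"
        outputs["sample_sheet"].to_csv(path, sep="\t", index=False)
        written.append(path)
    if "truth" in outputs:
        path = directory / "truth.json"
        payload = [
            {"patient_id": t.patient_id, "position": t.position,
             "status": t.status, "true_levels": t.true_levels}
            for t in outputs["truth"]
        ]
        with open(path, "w") as out:
            json.dump(payload, out, indent=1, sort_keys=True)
        written.append(path)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
    }
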