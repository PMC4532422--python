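"""Patient-level multi-tissue heteroplasmy analysis.

Each patient contributes several tissue samples (benign resection margin,
blood, primary tumor, recurrence, lymph-node metastasis, ...).  A variant
observed in a patient is summarised as one :class:`TissueVariantRecord`
holding its level (percentage of the rCRS-non-reference nucleotide) per tissue
class, with two explicit missingness marks:

``n.a.``  the tissue was not available / not sampled;
``n.d.``  the tissue was sequenced but the heteroplasmy was not detected above
          the 1% dual-strand threshold.

Records are classified as germline (homoplasmic or heteroplasmic) versus
somatic (shared between cancerous tissues or private), heteroplasmy dynamics
are summarised per tissue class, level distributions compared between benign
and tumor samples (uncorrected 2x2 chi-square), mutational spectra tallied per
gene region, and major/minor contamination-QC profiles split per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caller import HeteroplasmyCall
from .errors import AnnotationError, InsufficientDataError
from .reference import (
    GeneAnnotation,
    VariantLabel,
    iupac_code,
    parse_variant_label,
)

NA = "n.a."  # tissue not available
ND = "n.d."  # not detected above the 1% threshold

TISSUE_CLASSES = (
    "benign_margin", "blood", "primary_tumor", "recurrence",
    "lymph_node_metastasis", "benign_lymph_node", "dysplasia", "second_primary",
)
CANCEROUS_CLASSES = frozenset(
    {"primary_tumor", "recurrence", "lymph_node_metastasis", "second_primary"}
)
BENIGN_CLASSES = frozenset(
    {"benign_margin", "blood", "benign_lymph_node", "dysplasia"}
)

STATUSES = (
    "germline_homoplasmic", "germline_heteroplasmy",
    "somatic_shared", "somatic_private",
)

#: minor component (in %) below which a detected level counts as homoplasmic
HOMOPLASMY_MINOR_BOUND = 1.0


@dataclass
class TissueSample:
    patient_id: str
    sample_id: str
    tissue_class: str
    calls: list[HeteroplasmyCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")


@dataclass
class TissueVariantRecord:
    """One variant of one patient with its level per tissue class."""

    patient_id: str
    variant: VariantLabel
    levels: dict[str, float | str]  # tissue_class -> level_pct | NA | ND
    status: str | None = None

    def detected(self) -> dict[str, float]:
        return {
            cls: lvl for cls, lvl in self.levels.items()
            if isinstance(lvl, (int, float))
        }

    def observed_classes(self) -> list[str]:
        return [cls for cls, lvl in self.levels.items() if lvl != NA]


def _is_heteroplasmic(level: float) -> bool:
    return min(level, 100.0 - level) >= HOMOPLASMY_MINOR_BOUND


def classify_variant(record: TissueVariantRecord) -> str:
    """Germline/somatic status of a per-patient variant record.

    * ``germline_homoplasmic`` — detected and homoplasmic in every observed
      tissue.
    * ``germline_heteroplasmy`` — detected in a benign-side tissue
      (margin/blood/benign node) and either also present in a cancerous tissue
      or detected in at least two benign-side tissues, with heteroplasmy
      somewhere.
    * ``somatic_shared`` — absent from all benign-side tissues but present in
      at least two cancerous tissues.
    * ``somatic_private`` — everything else (typically a single-tissue
      heteroplasmy).

    ``n.d.`` counts as absence; ``n.a.`` tissues are ignored entirely.
    """
    observed = record.observed_classes()
    if not observed:
        raise InsufficientDataError(
            f"{record.variant}: no tissue observed for {record.patient_id}"
        )
    detected = record.detected()
    if not detected:
        raise InsufficientDataError(
            f"{record.variant}: not detected in any observed tissue"
        )
    benign_det = {c: v for c, v in detected.items() if c in BENIGN_CLASSES}
    cancer_det = {c: v for c, v in detected.items() if c in CANCEROUS_CLASSES}
    any_het = any(_is_heteroplasmic(v) for v in detected.values())
    if not any_het and len(detected) == len(observed):
        return "germline_homoplasmic"
    if benign_det:
        benign_het = any(_is_heteroplasmic(v) for v in benign_det.values())
        if (benign_het or any_het) and (cancer_det or len(benign_det) >= 2):
            return "germline_heteroplasmy"
        return "somatic_private"
    if len(cancer_det) >= 2:
        return "somatic_shared"
    return "somatic_private"


def classify_records(records: Iterable[TissueVariantRecord]) -> list[TissueVariantRecord]:
    """Classify records in place (status attribute) and return them."""
    records = list(records)
    for record in records:
        record.status = classify_variant(record)
    return records


# ---------------------------------------------------------------------------
# Level summaries and dynamics
# ---------------------------------------------------------------------------

def shared_somatic_summary(
    records: Iterable[TissueVariantRecord],
) -> dict[str, dict[str, float]]:
    """Mean level per tissue class over somatic mutations shared between
    tissues (``somatic_shared`` records); classes without observations are
    omitted and listed under the ``"omitted"`` key.
    """
    records = classify_records(records)
    shared = [r for r in records if r.status == "somatic_shared"]
    if not shared:
        raise InsufficientDataError("no shared somatic records")
    by_class: dict[str, list[float]] = {}
    for record in shared:
        for cls, level in record.detected().items():
            by_class.setdefault(cls, []).append(level)
    summary: dict[str, dict[str, float]] = {
        cls: {"mean": float(np.mean(levels)), "n": len(levels)}
        for cls, levels in by_class.items()
    }
    summary["omitted"] = sorted(set(TISSUE_CLASSES) - set(by_class))
    return summary


def expansion_summary(
    records: Iterable[TissueVariantRecord],
    patient_id: str,
    from_class: str,
    to_class: str,
) -> dict:
    """Per-patient heteroplasmy trajectory between two tissue classes.

    Uses every record of the patient with a detected level in both classes and
    reports per-site deltas/ratios plus summary statistics: the ratio of the
    class means, the mean increase over increasing sites and the mean decrease
    over decreasing sites.
    """
    sites = []
    for record in records:
        if record.patient_id != patient_id:
            continue
        det = record.detected()
        if from_class in det and to_class in det:
            sites.append((record.variant.format(), det[from_class], det[to_class]))
    if not sites:
        raise InsufficientDataError(
            f"no sites with levels in both {from_class} and {to_class} "
            f"for {patient_id}"
        )
    frm = np.array([s[1] for s in sites])
    to = np.array([s[2] for s in sites])
    delta = to - frm
    increases = delta[delta > 0]
    decreases = -delta[delta < 0]
    return {
        "patient_id": patient_id,
        "n_sites": len(sites),
        "sites": [
            {"variant": v, from_class: f, to_class: t, "delta": t - f,
             "ratio": t / f if f else float("inf")}
            for v, f, t in sites
        ],
        "mean_from": float(frm.mean()),
        "mean_to": float(to.mean()),
        "ratio_of_means": float(to.mean() / frm.mean()),
        "mean_increase": float(increases.mean()) if increases.size else None,
        "n_increase": int(increases.size),
        "mean_decrease": float(decreases.mean()) if decreases.size else None,
        "n_decrease": int(decreases.size),
    }


def high_level_fraction(levels: Sequence[float], boundary: float = 10.0) -> float:
    """Percentage of levels strictly above the boundary (default 10%)."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise InsufficientDataError("no levels supplied")
    return 100.0 * float((levels > boundary).mean())


@dataclass(frozen=True)
class LevelDistributionTest:
    counts: tuple[tuple[int, int], tuple[int, int]]  # (low, high) per group
    chi2: float
    p: float
    prop_low_a: float  # % of group A below the boundary
    prop_low_b: float
    bins_a: np.ndarray | None = None
    bins_b: np.ndarray | None = None
    bin_edges: np.ndarray | None = None


def level_distribution_test_from_counts(
    low_a: int, n_a: int, low_b: int, n_b: int,
) -> LevelDistributionTest:
    """Uncorrected Pearson chi-square on a low/high 2x2 table given counts."""
    if n_a <= 0 or n_b <= 0:
        raise InsufficientDataError("both groups must be non-empty")
    table = np.array([[low_a, n_a - low_a], [low_b, n_b - low_b]])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return LevelDistributionTest(
        counts=((low_a, n_a - low_a), (low_b, n_b - low_b)),
        chi2=float(chi2),
        p=float(p),
        prop_low_a=100.0 * low_a / n_a,
        prop_low_b=100.0 * low_b / n_b,
    )


def level_distribution_test(
    benign_levels: Sequence[float],
    tumor_levels: Sequence[float],
    boundary: float = 10.0,
    bin_width: float = 1.0,
) -> LevelDistributionTest:
    """Compare heteroplasmy-level distributions between benign and tumor
    samples: low/high 2x2 chi-square without continuity correction, plus
    1%-wide binned frequency distributions of the raw levels.
    """
    a = np.asarray(benign_levels, dtype=float)
    b = np.asarray(tumor_levels, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    base = level_distribution_test_from_counts(
        int((a < boundary).sum()), a.size, int((b < boundary).sum()), b.size,
    )
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    hist_a, _ = np.histogram(a, bins=edges)
    hist_b, _ = np.histogram(b, bins=edges)
    return LevelDistributionTest(
        counts=base.counts, chi2=base.chi2, p=base.p,
        prop_low_a=base.prop_low_a, prop_low_b=base.prop_low_b,
        bins_a=hist_a, bins_b=hist_b, bin_edges=edges,
    )


# ---------------------------------------------------------------------------
# Mutational spectrum across gene regions
# ---------------------------------------------------------------------------

def region_spectrum(
    somatic_positions: Sequence[int],
    inherited_positions: Sequence[int],
    annotation: GeneAnnotation | None = None,
    pool_trna: bool = True,
) -> pd.DataFrame:
    """Per-region counts and proportions of somatic and inherited variants.

    The default grouping keeps each protein gene and each rRNA as its own
    region, pools all tRNAs into one ``tRNA`` group, and pools the control
    region with the non-coding spacers into ``control``.  ``length_fraction``
    is each group's share of the 16,569-bp genome, for correlating variant
    burden with gene size.
    """
    annotation = annotation or GeneAnnotation.default()

    def group_of(position: int) -> str:
        region = annotation.locate(position)
        if pool_trna and region.region_class == "tRNA":
            return "tRNA"
        if region.region_class == "control":
            return "control"
        return region.name

    groups: dict[str, float] = {}
    for region in annotation:
        if pool_trna and region.region_class == "tRNA":
            key = "tRNA"
        elif region.region_class == "control":
            key = "control"
        else:
            key = region.name
        groups[key] = groups.get(key, 0.0) + region.length

    rows = {}
    for key, length in sorted(groups.items()):
        rows[key] = {
            "length_bp": int(length),
            "length_fraction": length / sum(groups.values()),
            "somatic_count": 0,
            "inherited_count": 0,
        }
    for pos in somatic_positions:
        rows[group_of(pos)]["somatic_count"] += 1
    for pos in inherited_positions:
        rows[group_of(pos)]["inherited_count"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    for kind in ("somatic", "inherited"):
        total = df[f"{kind}_count"].sum()
        df[f"{kind}_prop"] = df[f"{kind}_count"] / total if total else np.nan
    df.index.name = "region"
    return df


def class_spectrum(
    positions: Sequence[int],
    annotation: GeneAnnotation | None = None,
) -> pd.DataFrame:
    """Variant proportions by broad region class (tRNA/rRNA/protein/control)."""
    annotation = annotation or GeneAnnotation.default()
    counts = {"tRNA": 0, "rRNA": 0, "protein": 0, "control": 0}
    for pos in positions:
        counts[annotation.locate(pos).region_class] += 1
    total = sum(counts.values())
    if total == 0:
        raise InsufficientDataError("no variant positions supplied")
    return pd.DataFrame({
        "count": counts,
        "proportion_pct": {k: 100.0 * v / total for k, v in counts.items()},
    })


@dataclass(frozen=True)
class SpectrumCorrelations:
    r_somatic_vs_inherited: float
    p_somatic_vs_inherited: float
    r_somatic_vs_length: float
    p_somatic_vs_length: float
    r_inherited_vs_length: float
    p_inherited_vs_length: float


def spectrum_correlations(
    spectrum: pd.DataFrame,
    length_on_protein_only: bool = True,
) -> SpectrumCorrelations:
    """Correlations among region-level variant proportions and gene lengths.

    Somatic-vs-inherited is computed over all regions; the two length
    correlations are restricted to protein-coding genes by default (regions
    whose name is not a pooled group).
    """
    from .agreement import pearson_r as _pearson

    if len(spectrum) < 3:
        raise InsufficientDataError("need at least 3 regions")
    r_si, p_si = _pearson(spectrum["somatic_prop"], spectrum["inherited_prop"])
    sub = spectrum
    if length_on_protein_only:
        pooled = {"tRNA", "control", "MT-RNR1", "MT-RNR2"}
        sub = spectrum.loc[[i for i in spectrum.index if i not in pooled]]
    r_sl, p_sl = _pearson(sub["somatic_prop"], sub["length_fraction"])
    r_il, p_il = _pearson(sub["inherited_prop"], sub["length_fraction"])
    return SpectrumCorrelations(r_si, p_si, r_sl, p_sl, r_il, p_il)


def nonsyn_enrichment(
    somatic_effects: Sequence[str],
    germline_effects: Sequence[str],
) -> dict:
    """Test enrichment of non-synonymous changes among somatic protein-region
    variants relative to germline ones.

    2x2 chi-square (uncorrected); Fisher's exact test is substituted when any
    expected cell count falls below 5.
    """
    def tally(effects: Sequence[str]) -> tuple[int, int]:
        nonsyn = sum(1 for e in effects if e == "nonsynonymous")
        syn = sum(1 for e in effects if e == "synonymous")
        return nonsyn, syn

    s_non, s_syn = tally(somatic_effects)
    g_non, g_syn = tally(germline_effects)
    table = np.array([[s_non, s_syn], [g_non, g_syn]])
    if table.sum() == 0 or table.sum(axis=1).min() == 0:
        raise InsufficientDataError("no protein-region variants in a group")
    expected = stats.contingency.expected_freq(table)
    if expected.min() < 5:
        odds, p = stats.fisher_exact(table)
        return {"table": table, "method": "fisher", "statistic": float(odds),
                "p": float(p)}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"table": table, "method": "chi2", "statistic": float(chi2),
            "p": float(p)}


# ---------------------------------------------------------------------------
# Contamination-QC profile splitting
# ---------------------------------------------------------------------------

def split_profiles(
    heteroplasmies: Sequence[HeteroplasmyCall],
    homoplasmies: Sequence[VariantLabel] = (),
) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """Split a sample into major/minor haplotype profiles for QC.

    Both profiles carry every homoplasmic variant (shared variants indicate no
    contamination); each heteroplasmy contributes its major allele to the
    major profile and its minor allele to the minor profile.  The union of the
    two profiles reconstructs the full variant set.
    """
    shared = [(v.position, v.alternate) for v in homoplasmies]
    major = sorted(shared + [(c.position, c.major_allele) for c in heteroplasmies])
    minor = sorted(shared + [(c.position, c.minor_allele) for c in heteroplasmies])
    return major, minor


# ---------------------------------------------------------------------------
# Record construction
# ---------------------------------------------------------------------------

def load_shared_mutation_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged multi-tissue level tables from a published 28-patient oral
    squamous cell carcinoma cohort: (shared somatic mutations, shared mutations
    considered germline)."""
    def _read(name: str) -> pd.DataFrame:
        with resources.as_file(
            resources.files("mitohet.data").joinpath(name)
        ) as path:
            return pd.read_csv(path, sep="\t", comment="#", dtype=str)

    return _read("shared_somatic_levels.tsv"), _read("germline_shared_levels.tsv")


_TABLE_CLASS_COLUMNS = {
    "benign": "benign_margin",
    "blood": "blood",
    "primary_tumor": "primary_tumor",
    "recurrence": "recurrence",
    "lymph_node_metastasis": "lymph_node_metastasis",
}


def records_from_level_table(df: pd.DataFrame) -> list[TissueVariantRecord]:
    """Parse a published-style level table (columns: patient, mutation, one
    column per tissue with level / n.a. / n.d.) into variant records."""
    records = []
    for _, row in df.iterrows():
        levels: dict[str, float | str] = {}
        for col, cls in _TABLE_CLASS_COLUMNS.items():
            if col not in df.columns:
                continue
            raw = str(row[col]).strip()
            if raw == NA:
                levels[cls] = NA
            elif raw == ND:
                levels[cls] = ND
            else:
                levels[cls] = float(raw)
        records.append(TissueVariantRecord(
            patient_id=str(row["patient"]),
            variant=parse_variant_label(str(row["mutation"])),
            levels=levels,
        ))
    return records


def records_from_calls(
    calls_by_sample: Mapping[str, Sequence[HeteroplasmyCall]],
    sample_sheet: pd.DataFrame,
) -> list[TissueVariantRecord]:
    """Aggregate per-sample calls into per-patient variant records.

    ``sample_sheet`` needs columns ``patient_id``, ``sample_id`` and
    ``tissue_class``.  A tissue class the patient lacks is marked ``n.a.``;
    a sampled tissue without a call at the position is marked ``n.d.``.
    When a patient has several samples of the same tissue class the maximum
    level is kept.
    """
    sheet = sample_sheet.set_index("sample_id")
    patients: dict[str, list[str]] = {}
    for sample_id, row in sheet.iterrows():
        patients.setdefault(str(row["patient_id"]), []).append(str(sample_id))
    records = []
    for patient_id, sample_ids in patients.items():
        sampled_classes = {str(sheet.loc[s, "tissue_class"]) for s in sample_ids}
        variant_info: dict[int, dict] = {}
        for sample_id in sample_ids:
            cls = str(sheet.loc[sample_id, "tissue_class"])
            for call in calls_by_sample.get(sample_id, []):
                info = variant_info.setdefault(
                    call.position, {"ref": call.ref_base, "alts": set(), "levels": {}}
                )
                alt = call.major_allele if call.major_allele != call.ref_base \
                    else call.minor_allele
                info["alts"].add(alt)
                prev = info["levels"].get(cls)
                if prev is None or call.level_pct > prev:
                    info["levels"][cls] = call.level_pct
        for position, info in sorted(variant_info.items()):
            alt = sorted(info["alts"])[0]
            try:
                observed = iupac_code(info["ref"], alt)
            except Exception as exc:  # ref==alt should not happen
                raise AnnotationError(
                    f"cannot label variant at {position}: {exc}"
                )
            label = VariantLabel(
                position=position, ref_base=info["ref"], observed=observed,
            )
            levels: dict[str, float | str] = {}
            for cls in TISSUE_CLASSES:
                if cls in info["levels"]:
                    levels[cls] = info["levels"][cls]
                elif cls in sampled_classes:
                    levels[cls] = ND
                else:
                    levels[cls] = NA
            records.append(TissueVariantRecord(
                patient_id=patient_id, variant=label, levels=levels,
            ))
    return records
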