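"""Synthetic reporter scans and cohorts with exported ground truth.

Two generators make the pipeline testable at desk scale without raw
instrument data:

``simulate_reporter_scan``
    Places the 18 TMTpro reporter peaks at their theoretical m/z with a
    resolving power scaled from the instrument's nominal value.  When a
    channel in an isotopolog pair reaches the saturation intensity the
    pair is replaced by a single merged peak at the intensity-weighted
    centroid (total intensity conserved) whose resolving power falls
    below the 45 K gate — the detector-saturation coalescence signature.

``simulate_cohort``
    Builds a multi-tissue cohort matching the 18-plex design (3 ages x
    2 sexes x 3 replicates per tissue) of protein log2 abundances with
    planted continuous-age slopes, stepwise (non-continuous) patterns,
    sex effects and age-by-sex / age-by-tissue interactions, then emits
    peptide-level S/N observations.  Peptide S/N includes an additive
    background floor, so dim peptides' log-scale trends are attenuated
    relative to their protein — the rationale for S/N filtering before
    coefficient estimation.

All randomness flows from explicit seeds; there is no global state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from plexquant.extraction import Ms2Scan, Peak
from plexquant.reference import channel_labels, isotopolog_pairs, reporter_table

__all__ = [
    "InstrumentModel",
    "CohortSpec",
    "ScanTruth",
    "simulate_reporter_scan",
    "simulate_cohort",
    "protein_matrix_from_peptides",
]


@dataclass(frozen=True)
class InstrumentModel:
    """Detector model for reporter-scan simulation.

    resolving_power_nominal
        FWHM resolving power at ``resolving_power_ref_mz``; Orbitrap-style
        1/sqrt(m/z) scaling is applied, so the default 80,000 at m/z 200
        gives ~99,000-101,000 in the reporter region — comfortably above
        the 45 K isotopolog gate.
    saturation_intensity
        Detector units at which a reporter ion saturates; a pair merges
        when either member reaches it.
    merged_resolution_range
        Resolving power of a merged peak is drawn uniformly from this
        range (below 45 K by construction, so the resolution filter's
        sensitivity to coalescence is testable).
    merged_centroid_bias
        Additive m/z offset applied to the intensity-weighted merged
        centroid, for reproducing asymmetric observed offsets; default 0.
    noise_log_mean, noise_log_sd
        Per-peak noise values are log-normal:
        exp(N(noise_log_mean, noise_log_sd)).
    """

    resolving_power_nominal: float = 80000.0
    resolving_power_ref_mz: float = 200.0
    saturation_intensity: float = 1e6
    merged_resolution_range: tuple[float, float] = (15000.0, 40000.0)
    merged_centroid_bias: float = 0.0
    noise_log_mean: float = np.log(100.0)
    noise_log_sd: float = 0.3

    def resolving_power_at(self, mz: float) -> float:
        return self.resolving_power_nominal * np.sqrt(self.resolving_power_ref_mz / mz)


@dataclass
class ScanTruth:
    """Ground truth for one simulated scan."""

    true_intensities: np.ndarray
    coalesced_pairs: tuple[tuple[str, str], ...]
    saturated_channels: tuple[str, ...]


def simulate_reporter_scan(
    true_intensities: Sequence[float],
    instrument: InstrumentModel | None = None,
    seed: int = 0,
    scan_id: str = "sim",
) -> tuple[Ms2Scan, ScanTruth]:
    """Simulate the reporter-ion region of one MS2 scan.

    Parameters
    ----------
    true_intensities
        18 non-negative per-channel intensities in channel order;
        zero means the channel produces no peak.
    """
    instrument = instrument or InstrumentModel()
    intensities = np.asarray(true_intensities, dtype=float)
    if intensities.shape != (18,):
        raise ValueError(
            f"expected 18 channel intensities, got shape {intensities.shape}"
        )
    if (intensities < 0).any():
        raise ValueError("intensities must be non-negative")

    rng = np.random.default_rng(seed)
    table = reporter_table()
    label_index = {c.label: i for i, c in enumerate(table)}
    saturated = intensities >= instrument.saturation_intensity

    in_merged: set[str] = set()
    coalesced: list[tuple[str, str]] = []
    peaks: list[Peak] = []

    def _noise() -> float:
        return float(np.exp(rng.normal(instrument.noise_log_mean, instrument.noise_log_sd)))

    for n_member, c_member in isotopolog_pairs():
        i_n, i_c = label_index[n_member.label], label_index[c_member.label]
        if not (saturated[i_n] or saturated[i_c]):
            continue
        if intensities[i_n] <= 0 or intensities[i_c] <= 0:
            continue  # single-member "pair" cannot merge
        total = intensities[i_n] + intensities[i_c]
        centroid = (
            intensities[i_n] * n_member.exact_mz + intensities[i_c] * c_member.exact_mz
        ) / total + instrument.merged_centroid_bias
        lo, hi = instrument.merged_resolution_range
        peaks.append(
            Peak(
                mz=centroid,
                intensity=total,
                noise=_noise(),
                resolution=float(rng.uniform(lo, hi)),
            )
        )
        in_merged.update((n_member.label, c_member.label))
        coalesced.append((n_member.label, c_member.label))

    for i, chan in enumerate(table):
        if chan.label in in_merged or intensities[i] <= 0:
            continue
        if saturated[i]:
            # saturated but unpaired (126/135N) or partner absent: the
            # peak stays in place with degraded resolving power
            lo, hi = instrument.merged_resolution_range
            resolution = float(rng.uniform(lo, hi))
        else:
            resolution = instrument.resolving_power_at(chan.exact_mz)
        peaks.append(
            Peak(
                mz=chan.exact_mz,
                intensity=intensities[i],
                noise=_noise(),
                resolution=resolution,
            )
        )

    scan = Ms2Scan(scan_id=scan_id, peaks=peaks)
    truth = ScanTruth(
        true_intensities=intensities,
        coalesced_pairs=tuple(coalesced),
        saturated_channels=tuple(
            c.label for i, c in enumerate(table) if saturated[i]
        ),
    )
    return scan, truth


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Design and effect-size specification for a synthetic cohort.

    Defaults mirror a single-batch TMTpro 18-plex tissue: 3 ages x 2
    sexes x 3 replicates = 18 samples mapped onto the 18 channels.
    Effect sizes are on the log2 scale; an age slope of ~0.04/month
    accumulates ~0.7 log2 units across 3-20 months, a typical strong
    aging signature, and step sizes of ~0.8 are comparable one-interval
    jumps.
    """

    ages: tuple[float, ...] = (3.0, 12.0, 20.0)
    sexes: tuple[str, ...] = ("F", "M")
    replicates: int = 3
    tissues: tuple[str, ...] = ("tissue1",)
    n_proteins: int = 1000
    frac_age_linear: float = 0.15
    age_slope_sd: float = 0.04
    frac_age_step: float = 0.05
    step_size: float = 0.8
    frac_sex: float = 0.10
    sex_effect_sd: float = 0.5
    frac_age_by_sex: float = 0.05
    frac_age_by_tissue: float = 0.05
    residual_sd: float = 0.2
    intercept_mean: float = 10.0
    intercept_sd: float = 1.5
    peptides_per_protein: int = 4
    peptide_offset_sd: float = 1.0
    peptide_noise_sd: float = 0.1
    sn_floor: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        if len(self.ages) < 2:
            raise ValueError("need at least 2 distinct ages")
        fracs = (
            self.frac_age_linear
            + self.frac_age_step
        )
        if fracs > 1:
            raise ValueError("age effect fractions sum above 1")

    @property
    def samples_per_tissue(self) -> int:
        return len(self.ages) * len(self.sexes) * self.replicates


# step patterns that are genuinely non-continuous over 3 ages
_STEP_PATTERNS = ("Up-Down", "Down-Up", "Flat-Up", "Flat-Down", "Up-Flat", "Down-Flat")
_STEP_DELTAS = {"Up": 1.0, "Down": -1.0, "Flat": 0.0}


def _design_frame(spec: CohortSpec) -> pd.DataFrame:
    labels = channel_labels()
    rows = []
    for tissue in spec.tissues:
        combos = list(
            itertools.product(spec.ages, spec.sexes, range(1, spec.replicates + 1))
        )
        for i, (age, sex, rep) in enumerate(combos):
            channel = labels[i % len(labels)]
            rows.append(
                {
                    "sample_id": f"{tissue}_a{age:g}_{sex}_r{rep}",
                    "channel": channel,
                    "age_months": age,
                    "sex": sex,
                    "tissue": tissue,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (peptide quant table, design table, truth table).

    The peptide table is wide: one row per (protein, peptide), one
    column per sample_id, values on the S/N scale.  The truth table has
    one row per (protein, tissue) listing every planted coefficient and
    the trend category.  Same spec (including seed) => identical output.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    design = _design_frame(spec)
    ages = np.asarray(spec.ages, dtype=float)
    age_center = ages.mean()
    n = spec.n_proteins

    # assign effect classes
    u = rng.uniform(size=n)
    is_linear = u < spec.frac_age_linear
    is_step = (u >= spec.frac_age_linear) & (
        u < spec.frac_age_linear + spec.frac_age_step
    )
    slopes = np.where(is_linear, rng.normal(0.0, spec.age_slope_sd, size=n), 0.0)
    # force planted linear slopes away from zero so "linear effect" means it
    min_slope = 0.5 * spec.age_slope_sd
    slopes = np.where(
        is_linear & (np.abs(slopes) < min_slope),
        np.sign(slopes + (slopes == 0)) * min_slope,
        slopes,
    )
    step_patterns = np.where(
        is_step, rng.choice(_STEP_PATTERNS, size=n), ""
    )
    has_sex = rng.uniform(size=n) < spec.frac_sex
    sex_coefs = np.where(has_sex, rng.normal(0.0, spec.sex_effect_sd, size=n), 0.0)
    has_axs = rng.uniform(size=n) < spec.frac_age_by_sex
    axs_coefs = np.where(has_axs, rng.normal(0.0, spec.age_slope_sd, size=n), 0.0)

    multi_tissue = len(spec.tissues) > 1
    has_axt = (rng.uniform(size=n) < spec.frac_age_by_tissue) if multi_tissue else np.zeros(n, bool)
    intercepts = rng.normal(spec.intercept_mean, spec.intercept_sd, size=n)

    protein_ids = [f"P{i:05d}" for i in range(n)]
    truth_rows = []
    sample_ids = design["sample_id"].tolist()
    # (protein, peptide) -> {sample_id: sn}, filled tissue by tissue
    peptide_cells: dict[tuple[str, str], dict[str, float]] = {}

    # per-tissue slope deviations for age-by-tissue proteins
    axt_dev = rng.normal(0.0, 2.0 * spec.age_slope_sd, size=(n, len(spec.tissues)))

    # precompute per-sample covariates per tissue
    for t_i, tissue in enumerate(spec.tissues):
        sub = design[design["tissue"] == tissue]
        age_v = sub["age_months"].to_numpy(float)
        male_v = (sub["sex"] == "M").to_numpy(float)
        # map each sample's age to its index among sorted ages
        age_idx = np.searchsorted(ages, age_v)

        step_means = np.zeros((n, len(ages)))
        for i in range(n):
            if is_step[i]:
                labels_i = step_patterns[i].split("-")
                means = np.concatenate(
                    [[0.0], np.cumsum([_STEP_DELTAS[l] * spec.step_size for l in labels_i])]
                )
                step_means[i] = means - means.mean()

        slope_t = slopes + np.where(has_axt, axt_dev[:, t_i], 0.0)
        mean_mat = (
            intercepts[:, None]
            + slope_t[:, None] * (age_v[None, :] - age_center)
            + step_means[:, age_idx]
            + sex_coefs[:, None] * male_v[None, :]
            + axs_coefs[:, None] * (age_v[None, :] - age_center) * male_v[None, :]
        )
        protein_log2 = mean_mat + rng.normal(0.0, spec.residual_sd, size=mean_mat.shape)

        for i, prot in enumerate(protein_ids):
            truth_rows.append(
                {
                    "protein": prot,
                    "tissue": tissue,
                    "effect_class": (
                        "linear" if is_linear[i] else ("step" if is_step[i] else "null")
                    ),
                    "age_slope": slope_t[i] if is_linear[i] else 0.0,
                    "step_pattern": step_patterns[i] if is_step[i] else "",
                    "sex_coef": sex_coefs[i],
                    "age_by_sex_coef": axs_coefs[i],
                    "age_by_tissue": bool(has_axt[i]),
                    "intercept": intercepts[i],
                }
            )

        pep_offsets = rng.normal(0.0, spec.peptide_offset_sd, size=(n, spec.peptides_per_protein))
        tissue_samples = sub["sample_id"].tolist()
        for p in range(spec.peptides_per_protein):
            noise = rng.normal(0.0, spec.peptide_noise_sd, size=protein_log2.shape)
            pep_log2 = protein_log2 + pep_offsets[:, p][:, None] + noise
            sn = np.exp2(pep_log2) + spec.sn_floor
            for i, prot in enumerate(protein_ids):
                key = (prot, f"{prot}_pep{p + 1}")
                peptide_cells.setdefault(key, {}).update(
                    zip(tissue_samples, sn[i])
                )

    index = pd.MultiIndex.from_tuples(
        sorted(peptide_cells), names=["protein", "peptide"]
    )
    peptides = pd.DataFrame(
        [peptide_cells[key] for key in index], index=index, columns=sample_ids
    )

    truth = pd.DataFrame(truth_rows)
    return peptides, design, truth


def protein_matrix_from_peptides(peptides: pd.DataFrame) -> pd.DataFrame:
    """Sum the peptide S/N table to a protein x sample matrix."""
    return peptides.groupby(level="protein", sort=True).sum()
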