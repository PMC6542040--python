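"""Synthetic paired serum/BALF peptidome data with known ground truth.

Generates a balanced two-fluid, three-dose design; latent per-animal log2
abundances with a controllable serum-BALF correlation; per-sample ion-event
tables with retention-time / drift / mass jitter and below-LOD censoring;
and noisy b/y fragment spectra of true database peptides.  Every stage is
deterministic under its seed, so the planted structure serves as the oracle
for the whole downstream pipeline.

Model sketch
------------
Each feature carries a class: ``null`` (flat), ``modulated`` (log2 shift in
dosed groups), ``exclusive`` (absent at dose 0), or ``lost`` (absent in
dosed groups).  Per feature and animal the latent log2 abundance is

    baseline(fluid) + effect(dose) + within-animal noise

where both the per-feature baselines and the per-animal noise are shared
between fluids with correlation ``cross_fluid_r``, so the pooled
feature-by-animal serum/BALF log-intensity correlation equals
``cross_fluid_r`` by construction.  BALF intensities are scaled by
``fluid_factor`` (default 0.3) to emulate the dilution of lavage fluid, and
events below ``lod`` are censored.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .mass import default_table, fragment_ladder, peptide_mh, ResidueTable

DEFAULT_CLASS_PROPS = {"null": 0.55, "modulated": 0.25, "exclusive": 0.12, "lost": 0.08}

RT_RANGE = (2.0, 63.0)  # within the 0-65 min gradient window
DRIFT_RANGE = (20, 180)  # integer bins within 0-200
MASS_RANGE = (1000.0, 7000.0)


def bundled_substrate_fasta() -> Path:
    """Path to the bundled toy substrate database (MEROPS/SignalP-tagged)."""
    return Path(
        importlib.resources.files("peptidome").joinpath("data/substrate_db.fasta")
    )


def bundled_reference_table() -> Path:
    """Path to the bundled reference peptide table (sequences + printed masses)."""
    return Path(
        importlib.resources.files("peptidome").joinpath("data/reference_peptides.tsv")
    )


@dataclass
class NoiseParams:
    """Jitter and contamination settings for ion-event emission.

    Jitter sigmas default to one-third of the clustering tolerances
    (rt 2 min, drift 4 bins, mass 12 ppm), making true co-cluster
    membership a ~3-sigma event.
    """

    sigma_rt: float = 0.4
    sigma_drift: float = 1.0
    sigma_ppm: float = 3.0
    noise_event_rate: float = 0.2


@dataclass
class GroundTruth:
    """Planted structure behind a simulated dataset."""

    features: pd.DataFrame  # feature_id, cls, peptide, rt, drift_bin, mass_da
    latent: pd.DataFrame  # rows (feature_id, animal, fluid) -> log2_abundance, present
    cross_fluid_r: float
    fluid_factor: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cross_fluid_r": self.cross_fluid_r,
            "fluid_factor": self.fluid_factor,
            "features": self.features.to_dict(orient="records"),
            "latent": self.latent.to_dict(orient="records"),
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh)


def generate_design(
    n_per_group: int = 6, doses: tuple[int, ...] = (0, 10, 40), seed: int | None = None
) -> pd.DataFrame:
    """Balanced paired design: one serum and one BALF sample per animal.

    ``seed`` is accepted for interface symmetry; the design is deterministic
    regardless.
    """
    if n_per_group < 2:
        raise ValueError(f"need at least 2 replicates per group, got {n_per_group}")
    rows = []
    for dose in doses:
        for rep in range(1, n_per_group + 1):
            animal = f"d{dose}_a{rep}"
            for fluid in io.FLUIDS:
                rows.append(
                    {
                        "sample": f"{fluid}_d{dose}_r{rep}",
                        "fluid": fluid,
                        "dose": dose,
                        "replicate": rep,
                        "animal": animal,
                    }
                )
    return pd.DataFrame(rows, columns=io.DESIGN_COLUMNS)


def _assign_classes(n_features: int, props: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    names = list(props)
    p = np.array([props[k] for k in names], dtype=float)
    if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions must lie in [0,1] and sum to 1, got {props}")
    # deterministic counts (largest-remainder), shuffled
    counts = np.floor(p * n_features).astype(int)
    rem = n_features - counts.sum()
    order = np.argsort(-(p * n_features - counts))
    counts[order[:rem]] += 1
    classes = np.repeat(names, counts)
    rng.shuffle(classes)
    return classes


def generate_feature_truth(
    db_fasta: str | Path,
    design: pd.DataFrame,
    n_features: int = 2000,
    class_props: dict[str, float] | None = None,
    effect_log2fc: float = 1.0,
    cross_fluid_r: float = 0.5,
    db_fraction: float = 0.25,
    baseline_log2_mean: float = 14.0,
    baseline_log2_sd: float = 2.0,
    within_log2_sd: float = 0.43,
    fluid_factor: float = 0.3,
    peptide_len_bounds: tuple[int, int] = (6, 40),
    seed: int = 0,
) -> GroundTruth:
    """Draw feature classes, centroids, and per-animal latent abundances.

    A fraction ``db_fraction`` of features is mapped to random subsequences
    of the substrate FASTA; those features get the peptide's theoretical MH+
    as their mass centroid and can later receive fragment spectra.  Dose
    effects scale linearly with dose up to ``effect_log2fc`` at the top
    dose.  ``within_log2_sd`` = 0.43 corresponds to a ~30% intensity CV.
    """
    if not -1.0 <= cross_fluid_r <= 1.0:
        raise ValueError(f"cross_fluid_r must be in [-1, 1], got {cross_fluid_r}")
    props = dict(class_props or DEFAULT_CLASS_PROPS)
    rng = np.random.default_rng(seed)
    records = io.read_fasta(db_fasta)

    classes = _assign_classes(n_features, props, rng)
    # signed per-feature effect: up/down split keeps sample medians stable
    direction = rng.choice([-1.0, 1.0], size=n_features)
    feature_effect = np.where(classes == "modulated", direction * effect_log2fc, 0.0)
    is_db = rng.random(n_features) < db_fraction
    peptides = np.full(n_features, "", dtype=object)
    masses = rng.uniform(*MASS_RANGE, size=n_features)
    lo, hi = peptide_len_bounds
    for i in np.flatnonzero(is_db):
        _, _, prot = records[rng.integers(len(records))]
        if len(prot) < lo:
            continue
        plen = int(rng.integers(lo, min(hi, len(prot)) + 1))
        start = int(rng.integers(0, len(prot) - plen + 1))
        pep = prot[start : start + plen]
        peptides[i] = pep
        masses[i] = peptide_mh(pep)

    features = pd.DataFrame(
        {
            "feature_id": [f"F{i:05d}" for i in range(n_features)],
            "cls": classes,
            "effect_log2fc": feature_effect,
            "peptide": peptides,
            "rt_min": rng.uniform(*RT_RANGE, size=n_features),
            "drift_bin": rng.integers(DRIFT_RANGE[0], DRIFT_RANGE[1], size=n_features),
            "mass_da": masses,
        }
    )

    animals = design[["animal", "dose"]].drop_duplicates().reset_index(drop=True)
    n_animals = len(animals)
    doses = np.sort(design["dose"].unique())
    top_dose = doses.max()

    r = cross_fluid_r
    sr, sq = np.sqrt(abs(r)), np.sqrt(1.0 - abs(r))
    sign = 1.0 if r >= 0 else -1.0

    # per-feature baselines, correlated at r between fluids
    g = rng.standard_normal(n_features)
    gs = rng.standard_normal(n_features)
    gb = rng.standard_normal(n_features)
    base_serum = baseline_log2_mean + baseline_log2_sd * (sr * g + sq * gs)
    base_balf = (
        baseline_log2_mean
        + baseline_log2_sd * (sign * sr * g + sq * gb)
        + np.log2(fluid_factor)
    )

    # per feature x animal noise, correlated at r between fluids
    z = rng.standard_normal((n_features, n_animals))
    es = rng.standard_normal((n_features, n_animals))
    eb = rng.standard_normal((n_features, n_animals))
    noise_serum = within_log2_sd * (sr * z + sq * es)
    noise_balf = within_log2_sd * (sign * sr * z + sq * eb)

    dose_arr = animals["dose"].to_numpy()
    effect = np.zeros((n_features, n_animals))
    if top_dose > 0:
        effect = feature_effect[:, None] * (dose_arr / top_dose)[None, :]

    present = np.ones((n_features, n_animals), dtype=bool)
    present[classes == "exclusive"] = dose_arr[None, :] > 0
    present[classes == "lost"] = dose_arr[None, :] == 0

    rows = []
    for fluid, base, noise in (
        ("serum", base_serum, noise_serum),
        ("BALF", base_balf, noise_balf),
    ):
        log2_ab = base[:, None] + effect + noise
        for j, animal in enumerate(animals["animal"]):
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": features["feature_id"],
                        "animal": animal,
                        "fluid": fluid,
                        "log2_abundance": log2_ab[:, j],
                        "present": present[:, j],
                    }
                )
            )
    latent = pd.concat(rows, ignore_index=True)
    return GroundTruth(
        features=features, latent=latent, cross_fluid_r=cross_fluid_r, fluid_factor=fluid_factor
    )


def emit_ion_events(
    truth: GroundTruth,
    design: pd.DataFrame,
    noise: NoiseParams | None = None,
    lod: float = 4096.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit jittered, censored ion events for every sample.

    Each truly present feature emits at most one event per sample; events
    with intensity below ``lod`` are dropped.  Unclusterable noise events
    are added uniformly over the RT x drift x mass box at
    ``noise.noise_event_rate`` times the true-event count.  The returned
    table carries a ``true_feature`` column ('' for noise events) for
    oracle-based testing; downstream stages ignore it.
    """
    if lod <= 0:
        raise ValueError(f"lod must be positive, got {lod}")
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    lat = truth.latent.merge(design, on=["animal", "fluid"], how="inner")
    lat = lat[lat["present"]].reset_index(drop=True)
    intensity = np.power(2.0, lat["log2_abundance"].to_numpy())
    keep = intensity >= lod
    lat = lat[keep].reset_index(drop=True)
    intensity = intensity[keep]

    feat = truth.features.set_index("feature_id")
    rt0 = feat.loc[lat["feature_id"], "rt_min"].to_numpy()
    dt0 = feat.loc[lat["feature_id"], "drift_bin"].to_numpy(dtype=float)
    m0 = feat.loc[lat["feature_id"], "mass_da"].to_numpy()

    n = len(lat)
    rt = rt0 + rng.normal(0.0, noise.sigma_rt, size=n) if noise.sigma_rt > 0 else rt0.copy()
    if noise.sigma_drift > 0:
        dt = dt0 + np.rint(rng.normal(0.0, noise.sigma_drift, size=n))
    else:
        dt = dt0.copy()
    if noise.sigma_ppm > 0:
        mass = m0 + rng.normal(0.0, noise.sigma_ppm * m0 / 1e6, size=n)
    else:
        mass = m0.copy()

    events = pd.DataFrame(
        {
            "sample": lat["sample"],
            "rt_min": rt,
            "drift_bin": dt.astype(int),
            "mass_da": mass,
            "intensity": intensity,
            "true_feature": lat["feature_id"],
        }
    )

    n_noise = int(round(noise.noise_event_rate * n))
    if n_noise > 0:
        samples = design["sample"].to_numpy()
        noise_events = pd.DataFrame(
            {
                "sample": samples[rng.integers(len(samples), size=n_noise)],
                "rt_min": rng.uniform(*RT_RANGE, size=n_noise),
                "drift_bin": rng.integers(DRIFT_RANGE[0], DRIFT_RANGE[1], size=n_noise),
                "mass_da": rng.uniform(*MASS_RANGE, size=n_noise),
                "intensity": lod * np.power(2.0, rng.uniform(0.0, 4.0, size=n_noise)),
                "true_feature": "",
            }
        )
        events = pd.concat([events, noise_events], ignore_index=True)

    events = events.sort_values(
        ["sample", "mass_da", "rt_min"], kind="mergesort"
    ).reset_index(drop=True)
    return events


def synthesize_spectra(
    peptides: list[str],
    table: ResidueTable | None = None,
    frag_sampling: float = 0.8,
    n_noise_peaks: int = 5,
    precursor_ppm_jitter: float = 2.0,
    product_ppm_jitter: float = 4.0,
    seed: int = 0,
) -> list[io.Spectrum]:
    """Noisy b/y spectra of true peptides.

    Each spectrum holds the peptide's MH+ jittered uniformly within
    ``precursor_ppm_jitter`` ppm and a random fraction ``frag_sampling`` of
    its theoretical b/y ladder jittered within ``product_ppm_jitter`` ppm,
    plus ``n_noise_peaks`` uniform noise peaks.
    """
    if not 0.0 < frag_sampling <= 1.0:
        raise ValueError(f"frag_sampling must be in (0, 1], got {frag_sampling}")
    table = table or default_table()
    rng = np.random.default_rng(seed)
    spectra = []
    for k, pep in enumerate(peptides):
        ladder = fragment_ladder(pep, table)
        theo = np.array(ladder.b + ladder.y)
        n_keep = max(2, int(round(frag_sampling * len(theo))))
        if frag_sampling >= 1.0:
            idx = np.arange(len(theo))
        else:
            idx = rng.choice(len(theo), size=min(n_keep, len(theo)), replace=False)
        frag_mz = theo[idx]
        if product_ppm_jitter > 0:
            frag_mz = frag_mz * (
                1.0 + rng.uniform(-product_ppm_jitter, product_ppm_jitter, size=len(idx)) * 1e-6
            )
        frag_int = rng.uniform(0.1, 1.0, size=len(idx))
        if n_noise_peaks > 0:
            lo, hi = float(theo.min()) * 0.8, float(theo.max()) * 1.1
            noise_mz = rng.uniform(lo, hi, size=n_noise_peaks)
            noise_int = rng.uniform(0.02, 0.3, size=n_noise_peaks)
            frag_mz = np.concatenate([frag_mz, noise_mz])
            frag_int = np.concatenate([frag_int, noise_int])
        prec = ladder.mh
        if precursor_ppm_jitter > 0:
            prec = prec * (1.0 + rng.uniform(-precursor_ppm_jitter, precursor_ppm_jitter) * 1e-6)
        spectra.append(
            io.Spectrum(
                spectrum_id=f"synth_{k:04d}",
                precursor_mh=prec,
                fragments=np.column_stack([frag_mz, frag_int]),
            )
        )
    return spectra


def simulate_dataset(
    out_dir: str | Path,
    db_fasta: str | Path | None = None,
    n_per_group: int = 6,
    doses: tuple[int, ...] = (0, 10, 40),
    n_features: int = 2000,
    cross_fluid_r: float = 0.5,
    effect_log2fc: float = 1.0,
    class_props: dict[str, float] | None = None,
    lod: float = 4096.0,
    noise: NoiseParams | None = None,
    n_spectra: int = 100,
    seed: int = 0,
) -> dict:
    """One-call simulation: design + truth + ion tables + spectra on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = Path(db_fasta) if db_fasta else bundled_substrate_fasta()
    ss = np.random.SeedSequence(seed)
    s_truth, s_events, s_spectra = (int(c.generate_state(1)[0]) for c in ss.spawn(3))

    design = generate_design(n_per_group, doses, seed)
    truth = generate_feature_truth(
        db,
        design,
        n_features=n_features,
        class_props=class_props,
        effect_log2fc=effect_log2fc,
        cross_fluid_r=cross_fluid_r,
        seed=s_truth,
    )
    events = emit_ion_events(truth, design, noise=noise, lod=lod, seed=s_events)

    db_peptides = [p for p in truth.features["peptide"] if p]
    spectra = synthesize_spectra(db_peptides[:n_spectra], seed=s_spectra)

    io.write_design(design, out / "design.tsv")
    io.write_ion_events(events, out / "ion_events.tsv")
    truth.to_json(out / "ground_truth.json")
    io.write_mgf(spectra, out / "spectra.mgf")
    return {
        "design": str(out / "design.tsv"),
        "ion_events": str(out / "ion_events.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
        "spectra": str(out / "spectra.mgf"),
        "n_samples": len(design),
        "n_events": len(events),
        "n_spectra": len(spectra),
    }
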