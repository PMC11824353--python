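"""Synthetic reference signatures and per-cancer mutation cohorts.

The generator realizes exactly the model the refitting stage assumes: each
patient carries a sparse set of active signatures (Bernoulli per-signature
activity), gamma-distributed exposure weights on the active set scaled to a
negative-binomially distributed mutation burden, and a motif catalog drawn
Multinomial(n_j, normalize(S @ e_j)).  Gamma exposure mixtures plus NB
burdens give the heavy-tailed abundance spread seen in real cohorts.  Every
generator is deterministic under its seed and records the ground truth it
emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CohortLabels, ExposureMatrix, MotifCatalog, N_MOTIFS, SignatureMatrix
from .motifs import MOTIF_ORDER, COMPLEMENT, parse_motif_label, reverse_complement

logger = logging.getLogger(__name__)

MIN_MUTATIONS = 50  # NNLS on fewer counts is too degenerate to be useful
MAX_SEPARATION_TRIES = 100
SIGNATURE_COSINE_CAP = 0.9

SCENARIOS = ("specific_skcm_analogue", "null_identical_types", "diverse_mixtures")


@dataclass
class CancerProfile:
    """Generative law for one cancer type's patients.

    ``activity_prob[i]`` is the chance signature i is active in a patient;
    active signatures get Gamma(exposure_shape, exposure_scale) weights,
    rescaled so exposures sum to the patient's mutation burden, which is
    NB(mean=n_mut_mean, dispersion=n_mut_dispersion) truncated at
    ``MIN_MUTATIONS``.
    """

    cancer_type: str
    activity_prob: np.ndarray
    exposure_shape: float = 2.0
    exposure_scale: float | np.ndarray = 1.0  # scalar or one scale per signature
    n_mut_mean: float = 2000.0
    n_mut_dispersion: float = 2.0
    region: str = "US"

    def __post_init__(self) -> None:
        self.activity_prob = np.asarray(self.activity_prob, dtype=float)
        if np.any((self.activity_prob < 0) | (self.activity_prob > 1)):
            raise ValueError("activity probabilities must lie in [0, 1]")
        self.exposure_scale = np.asarray(self.exposure_scale, dtype=float)
        if np.any(self.exposure_scale <= 0):
            raise ValueError("exposure_scale must be positive")
        for name in ("exposure_shape", "n_mut_mean", "n_mut_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scale_vector(self, K: int) -> np.ndarray:
        return np.broadcast_to(self.exposure_scale, (K,)).astype(float)


@dataclass
class SyntheticTruth:
    exposures: ExposureMatrix
    labels: CohortLabels
    seed: int
    config: dict = field(default_factory=dict)


def make_reference_signatures(
    K: int, sparsity_concentration: float = 0.1, seed: int = 0
) -> SignatureMatrix:
    """K Dirichlet-drawn signature profiles over the 96 motifs.

    Concentration < 1 gives peaked, COSMIC-like profiles.  Columns whose
    cosine to an earlier column reaches 0.9 are resampled (up to 100 tries)
    so the panel is identifiable.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = np.full(N_MOTIFS, sparsity_concentration)
    cols: list[np.ndarray] = []
    for _ in range(K):
        for attempt in range(MAX_SEPARATION_TRIES):
            cand = rng.dirichlet(alpha)
            u = cand / np.linalg.norm(cand)
            if all(float(u @ (c / np.linalg.norm(c))) < SIGNATURE_COSINE_CAP for c in cols):
                cols.append(cand)
                break
        else:
            raise RuntimeError(
                "could not draw sufficiently separated signatures in "
                f"{MAX_SEPARATION_TRIES} tries; decrease sparsity_concentration"
            )
    ids = [f"S{i + 1:02d}" for i in range(K)]
    return SignatureMatrix(ids, np.stack(cols, axis=1))


def _draw_burden(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # NB with mean m and dispersion r: var = m + m^2/r; numpy n=r, p=r/(r+m)
    p = dispersion / (dispersion + mean)
    n = int(rng.negative_binomial(dispersion, p))
    return max(n, MIN_MUTATIONS)


def simulate_cohort(
    profiles: list[CancerProfile],
    sig: SignatureMatrix,
    n_per_type: int,
    seed: int = 0,
    split: str = "train",
) -> tuple[MotifCatalog, SyntheticTruth]:
    """Draw ``n_per_type`` patients per profile with recorded ground truth."""
    K = sig.n_signatures
    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    true_exposures: list[np.ndarray] = []
    label_records: dict[str, tuple[str, str, str]] = {}
    for profile in profiles:
        if profile.activity_prob.size != K:
            raise ValueError(
                f"profile {profile.cancer_type} has {profile.activity_prob.size} "
                f"activity entries for {K} signatures"
            )
        for i in range(n_per_type):
            active = rng.random(K) < profile.activity_prob
            if not active.any():
                forced = int(np.argmax(profile.activity_prob))
                active[forced] = True
                logger.debug(
                    "patient of %s drew an empty active set; forcing signature %d",
                    profile.cancer_type,
                    forced,
                )
            weights = np.zeros(K)
            scales = profile.scale_vector(K)
            weights[active] = rng.gamma(profile.exposure_shape, scales[active])
            if weights.sum() == 0:  # measure-zero gamma corner
                weights[active] = 1.0
            n_mut = _draw_burden(rng, profile.n_mut_mean, profile.n_mut_dispersion)
            exposures = weights * (n_mut / weights.sum())
            probs = sig.profiles @ (exposures / n_mut)
            probs = probs / probs.sum()
            counts = rng.multinomial(n_mut, probs)
            sid = f"{profile.cancer_type}_{split}_{i:04d}"
            sample_ids.append(sid)
            columns.append(counts)
            true_exposures.append(exposures)
            label_records[sid] = (profile.cancer_type, profile.region, split)
    counts = (
        np.stack(columns, axis=1) if columns else np.zeros((N_MOTIFS, 0), dtype=np.int64)
    )
    catalog = MotifCatalog(sample_ids, counts)
    truth = SyntheticTruth(
        exposures=ExposureMatrix(
            list(sig.signature_ids),
            sample_ids,
            np.stack(true_exposures, axis=1) if true_exposures else np.zeros((K, 0)),
        ),
        labels=CohortLabels.from_records(label_records),
        seed=seed,
        config={
            "n_per_type": n_per_type,
            "split": split,
            "profiles": [
                {
                    "cancer_type": p.cancer_type,
                    "activity_prob": p.activity_prob.tolist(),
                    "exposure_shape": p.exposure_shape,
                    "exposure_scale": np.asarray(p.exposure_scale).tolist(),
                    "n_mut_mean": p.n_mut_mean,
                    "n_mut_dispersion": p.n_mut_dispersion,
                    "region": p.region,
                }
                for p in profiles
            ],
        },
    )
    return catalog, truth


def emit_maf(
    catalog: MotifCatalog,
    seed: int = 0,
    labels: CohortLabels | None = None,
    path=None,
) -> pd.DataFrame:
    """Expand a catalog into MAF-like SNV rows with inline 3-mer contexts.

    Positions are synthetic running coordinates; about half the rows are
    emitted on the purine strand (reverse-complemented context, complemented
    alleles) to exercise pyrimidine collapsing.  Rebuilding a catalog from
    the output reproduces the input exactly.
    """
    rng = np.random.default_rng(seed)
    motifs = [parse_motif_label(lbl) for lbl in MOTIF_ORDER]
    rows = []
    position = 0
    for j, sid in enumerate(catalog.sample_ids):
        lab = labels.table.loc[sid] if labels is not None else None
        for idx in np.flatnonzero(catalog.counts[:, j]):
            m = motifs[idx]
            for _ in range(int(catalog.counts[idx, j])):
                position += 2  # keep loci distinct
                context = m.five_prime + m.ref_base + m.three_prime
                ref, alt = m.ref_base, m.alt_base
                if rng.random() < 0.5:  # emit on the purine strand
                    context = reverse_complement(context)
                    ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
                row = {
                    "sample": sid,
                    "chromosome": "chrS",
                    "position": position,
                    "ref": ref,
                    "alt": alt,
                    "context": context,
                }
                if lab is not None:
                    row["cancer_type"] = lab["cancer_type"]
                    row["region"] = lab["region"]
                rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["sample", "chromosome", "position", "ref", "alt", "context"]
        + (["cancer_type", "region"] if labels is not None else []),
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


@dataclass
class ScenarioBundle:
    name: str
    seed: int
    signatures: SignatureMatrix
    train_catalog: MotifCatalog
    train_truth: SyntheticTruth
    test_catalog: MotifCatalog
    test_truth: SyntheticTruth
    profiles: list[CancerProfile]


_TEST_REGIONS = ("AU", "EU", "JP", "KR", "CN")


def _scenario_profiles(
    name: str, K: int, rng: np.random.Generator, n_mut_mean: float
) -> list[CancerProfile]:
    cancer_types = ["SKCM", "BRCA", "LIHC", "LUSC", "STAD"]
    profiles = []
    if name == "specific_skcm_analogue":
        for t, cancer in enumerate(cancer_types):
            prob = np.zeros(K)
            scale = np.ones(K)
            if cancer == "SKCM":
                prob[0] = 0.95  # exclusive, UV-like signature
                prob[K // 2 :] = 0.3
                scale[0] = 10.0  # the exclusive signature dominates the burden
            else:
                prob[1 : K // 2] = 0.5
                prob[K // 2 :] = 0.35 + 0.02 * t  # shared mixtures, mild variation
            profiles.append(
                CancerProfile(cancer, prob, exposure_scale=scale, n_mut_mean=n_mut_mean)
            )
    elif name == "null_identical_types":
        prob = np.full(K, 0.4)
        for cancer in cancer_types:
            profiles.append(CancerProfile(cancer, prob.copy(), n_mut_mean=n_mut_mean))
    elif name == "diverse_mixtures":
        for cancer in cancer_types:
            prob = rng.uniform(0.1, 0.8, size=K)
            profiles.append(CancerProfile(cancer, prob, n_mut_mean=n_mut_mean))
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    return profiles


def make_benchmark_scenario(
    name: str,
    seed: int = 0,
    K: int = 10,
    n_per_type: int = 60,
    n_mut_mean: float = 2000.0,
) -> ScenarioBundle:
    """Train + test cohorts from shared profiles with a test-side shift.

    The test cohort is drawn from the same profiles with each cancer type's
    exposure scale perturbed by up to +/-10% and a non-US region code,
    emulating an independent external population.
    """
    master = np.random.default_rng(seed)
    sig_seed, train_seed, test_seed, profile_seed, shift_seed = (
        int(s) for s in master.integers(0, 2**31 - 1, size=5)
    )
    signatures = make_reference_signatures(K, sparsity_concentration=0.1, seed=sig_seed)
    profiles = _scenario_profiles(
        name, K, np.random.default_rng(profile_seed), n_mut_mean
    )
    train_catalog, train_truth = simulate_cohort(
        profiles, signatures, n_per_type, seed=train_seed, split="train"
    )
    shift_rng = np.random.default_rng(shift_seed)
    test_profiles = []
    for t, p in enumerate(profiles):
        # per-signature scale jitter: shifts mixture proportions, not just totals
        jitter = 1.0 + shift_rng.uniform(-0.1, 0.1, size=K)
        q = CancerProfile(
            p.cancer_type,
            p.activity_prob.copy(),
            exposure_shape=p.exposure_shape,
            exposure_scale=p.scale_vector(K) * jitter,
            n_mut_mean=p.n_mut_mean,
            n_mut_dispersion=p.n_mut_dispersion,
            region=_TEST_REGIONS[t % len(_TEST_REGIONS)],
        )
        test_profiles.append(q)
    test_catalog, test_truth = simulate_cohort(
        test_profiles, signatures, n_per_type, seed=test_seed, split="test"
    )
    return ScenarioBundle(
        name=name,
        seed=seed,
        signatures=signatures,
        train_catalog=train_catalog,
        train_truth=train_truth,
        test_catalog=test_catalog,
        test_truth=test_truth,
        profiles=profiles,
    )
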