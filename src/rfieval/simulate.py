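"""Synthetic herd generator.

Produces multi-generation pedigrees, gene-dropped SNP genotypes, true
breeding values drawn from the pedigree relationship matrix, and daily
heifer/cow records with the fixed-effect structure the downstream phenotype
models assume.  Everything is reproducible bit-for-bit from a seed.

Day-level measurement noise is uniform on [-sqrt(3)*sd, sqrt(3)*sd] (same
variance as a Gaussian of that sd but bounded below 3 sd), so that the 3-SD
outlier rule has a clean ground truth: with ``outlier_rate=0`` no clean
record can trip it, and injected outliers are the only removals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_true_breeding_values",
    "simulate_cow_daily_records",
    "simulate_heifer_records",
    "simulate_group_pedigree",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_pedigree(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Simulate a multi-generation pedigree with reused sires.

    Returns a DataFrame with columns ``animal, sire, dam, sex, generation``,
    sorted parents-before-offspring; 0 denotes an unknown parent.  Founders
    (generation 0) have both parents unknown.  A small fraction of males
    (``config.sire_fraction``) is used as sires each generation, creating the
    paternal half-sib families the cohort analyses rely on.
    """
    rng = _rng(config.seed if seed is None else seed)
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if config.n_generations < 1:
        raise ValueError("need at least 1 generation")

    n_off = config.n_offspring_per_generation or config.n_founders
    animal, sire, dam, sex, gen = [], [], [], [], []
    next_id = 1

    founders_sex = rng.choice(["M", "F"], size=config.n_founders)
    if config.n_generations > 1:
        # a breeding population needs both sexes among founders
        if (founders_sex == "M").sum() == 0 or (founders_sex == "F").sum() == 0:
            founders_sex[0], founders_sex[-1] = "M", "F"
    for _ in range(config.n_founders):
        animal.append(next_id)
        sire.append(0)
        dam.append(0)
        gen.append(0)
        next_id += 1
    sex.extend(founders_sex.tolist())

    prev_ids = np.array(animal)
    prev_sex = founders_sex
    for g in range(1, config.n_generations):
        males = prev_ids[prev_sex == "M"]
        females = prev_ids[prev_sex == "F"]
        if len(males) == 0 or len(females) == 0:
            raise ValueError(
                f"impossible mating structure: generation {g - 1} has "
                f"{len(males)} males and {len(females)} females"
            )
        n_sires = max(1, int(round(config.sire_fraction * len(males))))
        sires = rng.choice(males, size=n_sires, replace=False)
        off_sire = rng.choice(sires, size=n_off, replace=True)
        off_dam = rng.choice(females, size=n_off, replace=True)
        off_sex = rng.choice(["M", "F"], size=n_off)
        if g < config.n_generations - 1 and (
            (off_sex == "M").sum() == 0 or (off_sex == "F").sum() == 0
        ):
            off_sex[0], off_sex[-1] = "M", "F"
        ids = np.arange(next_id, next_id + n_off)
        next_id += n_off
        animal.extend(ids.tolist())
        sire.extend(off_sire.tolist())
        dam.extend(off_dam.tolist())
        sex.extend(off_sex.tolist())
        gen.extend([g] * n_off)
        prev_ids, prev_sex = ids, off_sex

    return pd.DataFrame(
        {"animal": animal, "sire": sire, "dam": dam, "sex": sex, "generation": gen}
    )


def simulate_genotypes(pedigree: pd.DataFrame, config: SimulationConfig, seed=None):
    """Gene-drop biallelic SNP genotypes through a pedigree.

    Founder genotypes are Binomial(2, p_j) with p_j drawn uniformly from
    ``config.maf_range``; each non-founder receives from each parent one
    allele, transmitted as Bernoulli(parent genotype / 2).  Genotypes are
    coded 0/1/2 copies of the counted allele.

    Returns a :class:`rfieval.relationships.GenotypeMatrix`.
    """
    from .relationships import GenotypeMatrix

    rng = _rng(config.seed + 1 if seed is None else seed)
    ids = pedigree["animal"].to_numpy()
    pos = {a: i for i, a in enumerate(ids)}
    n, m = len(ids), config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=m)
    M = np.zeros((n, m), dtype=np.int8)
    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    for i in range(n):
        s, d = sires[i], dams[i]
        if s == 0 and d == 0:
            M[i] = rng.binomial(2, p)
        else:
            # unknown single parent contributes a population allele
            ps = M[pos[s]] / 2.0 if s != 0 else p
            pd_ = M[pos[d]] / 2.0 if d != 0 else p
            M[i] = rng.binomial(1, ps) + rng.binomial(1, pd_)
    chrom = np.array(
        [str(1 + i % config.n_chromosomes) for i in range(m)], dtype=object
    )
    snp_ids = np.array([f"snp{j + 1}" for j in range(m)], dtype=object)
    return GenotypeMatrix(ids=ids.copy(), snp_ids=snp_ids, chrom=chrom, matrix=M)


def _psd_sqrt(mat: np.ndarray, name: str) -> np.ndarray:
    """Matrix square root for a PSD matrix: Cholesky when positive definite,
    else an eigenvalue square root, clipping the tiny negative eigenvalues
    (within a 1e-6 relative jitter band) that exact singularity produces
    numerically; genuinely indefinite input fails."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        pass
    scale = max(np.mean(np.diag(mat)), 1e-300)
    w, V = np.linalg.eigh(mat)
    if w.min() < -1e-6 * scale:
        raise ValueError(f"{name} is not positive semi-definite (min eig {w.min():g})")
    return V * np.sqrt(np.clip(w, 0, None))


def simulate_true_breeding_values(
    relationship: np.ndarray, K, seed=None
) -> np.ndarray:
    """Draw true breeding values from N(0, relationship ⊗ K).

    ``K`` may be a scalar additive variance (univariate) or a t x t trait
    (co)variance matrix.  Returns an (n_animals, n_traits) array (squeezed to
    1-D in the univariate case).  Animal i and j covary as A_ij * K.
    """
    rng = _rng(seed)
    A = np.asarray(relationship, dtype=float)
    K = np.atleast_2d(np.asarray(K, dtype=float))
    n, t = A.shape[0], K.shape[0]
    if not np.allclose(K, K.T, atol=1e-12):
        raise ValueError("K must be symmetric")
    if np.allclose(K, 0):
        out = np.zeros((n, t))
        return out[:, 0] if t == 1 else out
    La = _psd_sqrt(A, "relationship")
    Lk = _psd_sqrt(K, "K")
    z = rng.standard_normal((n, t))
    u = La @ z @ Lk.T
    return u[:, 0] if t == 1 else u


# ---------------------------------------------------------------------------
# daily records


def _uniform_noise(rng, sd, size):
    """Zero-mean noise with standard deviation ``sd``, bounded within
    sqrt(3) sd (< 3 sd) so clean records never trip the 3-SD rule."""
    half = np.sqrt(3.0) * sd
    return rng.uniform(-half, half, size=size)


# fixed-effect regression coefficients used to build daily DMI; the cow RFI
# model regresses average DMI on exactly these covariates, so the residual is
# the animal effect plus averaged day noise.
_COW_BETA = {
    "dim": 0.02,
    "dim2": -4e-5,
    "age": 1e-3,
    "age2": -2e-7,
    "bw": 0.01,
    "ecm": 0.35,
    "dbw": 0.2,
}


def simulate_cow_daily_records(
    animal_ids,
    tbv_cow,
    config: SimulationConfig,
    seed=None,
    dim_range: tuple[int, int] = (100, 240),
) -> pd.DataFrame:
    """Simulate daily lactating-cow records over days in milk 100-240.

    Each cow gets a trial (26 levels), a lactation (1 or 2), an age at
    calving, and daily body weight, milk yield, fat %, protein % and
    dry-matter intake.  DMI is built from the same covariates the cow RFI
    model fits (trial, lactation, DIM, DIM^2, age, age^2, BW, ECM, ΔBW) plus
    the animal's true RFI deviation (breeding value + permanent environment)
    and bounded day noise.  A fraction ``config.outlier_rate`` of days is
    perturbed beyond the 3-SD rule: DMI-only, BW-only, ECM-only (via fat %),
    and DMI+MY same-direction co-outliers that the QC exception must retain.

    Returns a tidy frame: animal_id, trial, lactation, age, dim, bw, my,
    fat_pct, prot_pct, dmi, outlier_kind.
    """
    rng = _rng(config.seed + 2 if seed is None else seed)
    animal_ids = np.asarray(animal_ids)
    tbv = np.asarray(tbv_cow, dtype=float)
    n = len(animal_ids)
    lo_dim, hi_dim = dim_range
    dims = np.arange(lo_dim, hi_dim + 1)
    nd = len(dims)

    trial_effects = rng.normal(0.0, 0.8, size=config.n_trials_cow)
    lact_effects = np.array([0.0, 3.9])  # parity-2 cows eat more

    # balanced randomization over trial levels so small herds still leave
    # every level estimable
    trial = rng.permutation(np.arange(n) % config.n_trials_cow)
    lact = np.where(
        rng.random(n) < config.second_lactation_fraction, 2, 1
    )
    if config.n_lactations == 1:
        lact[:] = 1
    age_calving = np.where(
        lact == 1, rng.normal(945, 87, size=n), rng.normal(1435, 152, size=n)
    ) - (lo_dim + hi_dim) / 2.0  # so that average age over the window matches

    # permanent-environment part of the cow RFI residual; day noise averages
    # out over ~140 d, so pe carries almost all of sigma_e2
    dmi_day_sd = 1.2
    pe_var = max(config.cow.residual - dmi_day_sd**2 / nd, 1e-12)
    pe = rng.normal(0.0, np.sqrt(pe_var), size=n)

    rows = []
    for i in range(n):
        bw0 = rng.normal(677, 75) if lact[i] == 1 else rng.normal(749, 67)
        bw_slope = rng.normal(0.5, 1.0) / 140.0
        bw = bw0 + bw_slope * (dims - lo_dim) + _uniform_noise(rng, 6.0, nd)
        my0 = rng.normal(34, 6) if lact[i] == 1 else rng.normal(40, 6)
        my = np.maximum(
            my0 - 0.05 * (dims - lo_dim) + _uniform_noise(rng, 1.5, nd), 0.1
        )
        fat = np.clip(rng.normal(4.3, 0.5) + _uniform_noise(rng, 0.12, nd), 1.5, 8.0)
        prot = np.clip(rng.normal(3.33, 0.15) + _uniform_noise(rng, 0.05, nd), 2.0, 5.0)
        age = age_calving[i] + dims
        ecm = 0.327 * my + 12.95 * fat * my / 100.0 + 7.2 * prot * my / 100.0
        dbw_total = bw_slope * (hi_dim - lo_dim)
        b = _COW_BETA
        dmi = (
            5.0
            + trial_effects[trial[i]]
            + lact_effects[lact[i] - 1]
            + b["dim"] * dims
            + b["dim2"] * dims**2
            + b["age"] * age
            + b["age2"] * age**2
            + b["bw"] * bw
            + b["ecm"] * ecm
            + b["dbw"] * dbw_total
            + tbv[i]
            + pe[i]
            + _uniform_noise(rng, dmi_day_sd, nd)
        )
        kind = np.array(["clean"] * nd, dtype=object)
        if config.outlier_rate > 0:
            n_out = rng.binomial(nd, config.outlier_rate)
            days = rng.choice(nd, size=n_out, replace=False)
            kinds = rng.choice(
                ["dmi", "bw", "ecm", "dmi_my"], size=n_out, p=[0.4, 0.25, 0.2, 0.15]
            )
            for d, k in zip(days, kinds):
                sign = 1 if rng.random() < 0.5 else -1
                if k == "dmi":
                    dmi[d] += sign * 8 * dmi_day_sd
                elif k == "bw":
                    bw[d] += sign * 8 * 6.0
                elif k == "ecm":
                    fat[d] += sign * 8 * 0.12 * 4  # moves ECM, not MY
                else:  # same-direction DMI and MY co-outlier
                    dmi[d] += sign * 8 * dmi_day_sd
                    my[d] += sign * 8 * 1.5
                kind[d] = k
            np.clip(my, 0.05, None, out=my)
            np.clip(fat, 0.1, None, out=fat)
            np.clip(dmi, 0.05, None, out=dmi)
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": animal_ids[i],
                    "trial": f"T{trial[i] + 1:02d}",
                    "lactation": lact[i],
                    "age": age,
                    "dim": dims,
                    "bw": bw,
                    "my": my,
                    "fat_pct": fat,
                    "prot_pct": prot,
                    "dmi": dmi,
                    "outlier_kind": kind,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


_HEIFER_BETA = {"adg": 1.5, "mbw": 0.09, "age": 2e-3}


def simulate_heifer_records(
    animal_ids, tbv_heifer, config: SimulationConfig, seed=None
):
    """Simulate heifer feed-trial records: serial (biweekly) body weights with
    linear growth, daily dry-matter intake, trial labels and ages.

    Ages are drawn within 206-437 d; growth slopes (true ADG) around
    1.09 kg/d.  Daily DMI is built from the heifer RFI covariates (ADG, MBW,
    age, trial mean) plus the animal's RFI deviation and bounded day noise.

    Returns ``(serial_bw, daily_dmi, meta)`` DataFrames:
    serial_bw: animal_id, day, bw; daily_dmi: animal_id, day, dmi;
    meta: animal_id, trial, age.
    """
    rng = _rng(config.seed + 3 if seed is None else seed)
    animal_ids = np.asarray(animal_ids)
    tbv = np.asarray(tbv_heifer, dtype=float)
    n = len(animal_ids)
    n_trials = max(1, int(np.ceil(n / config.heifer_trial_size)))
    trial_idx = rng.permutation(np.arange(n) % n_trials)
    trial_effects = rng.normal(0.0, 0.4, size=n_trials)

    days = np.arange(0, config.heifer_test_days + 1)
    weigh_days = days[:: config.bw_weigh_interval]
    if weigh_days[-1] != days[-1]:
        weigh_days = np.append(weigh_days, days[-1])

    age = np.clip(rng.normal(307, 43, size=n), 206, 437)
    adg_true = np.clip(rng.normal(1.09, 0.24, size=n), 0.2, 2.7)
    bw0 = np.clip(rng.normal(234, 30, size=n), 120, 400)

    dmi_day_sd = 0.8
    nd = len(days)
    pe_var = max(config.heifer.residual - dmi_day_sd**2 / nd, 1e-12)
    pe = rng.normal(0.0, np.sqrt(pe_var), size=n)

    sb_rows, dmi_rows, meta_rows = [], [], []
    for i in range(n):
        bw_true = bw0[i] + adg_true[i] * days
        sb = bw_true[weigh_days] + _uniform_noise(rng, 4.0, len(weigh_days))
        mbw = float(np.mean(bw_true**0.75))
        b = _HEIFER_BETA
        mu = (
            -1.5
            + trial_effects[trial_idx[i]]
            + b["adg"] * adg_true[i]
            + b["mbw"] * mbw
            + b["age"] * age[i]
            + tbv[i]
            + pe[i]
        )
        dmi = np.maximum(mu + _uniform_noise(rng, dmi_day_sd, nd), 0.1)
        sb_rows.append(
            pd.DataFrame({"animal_id": animal_ids[i], "day": weigh_days, "bw": sb})
        )
        dmi_rows.append(
            pd.DataFrame({"animal_id": animal_ids[i], "day": days, "dmi": dmi})
        )
        meta_rows.append(
            {
                "animal_id": animal_ids[i],
                "trial": f"H{trial_idx[i] + 1:03d}",
                "age": age[i],
            }
        )
    return (
        pd.concat(sb_rows, ignore_index=True),
        pd.concat(dmi_rows, ignore_index=True),
        pd.DataFrame(meta_rows),
    )


def simulate_group_pedigree(
    n_sires: int = 8,
    n_per_family: int = 10,
    n_dams_per_line: int = 40,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Build a pedigree with an explicit training set and candidate Groups 1-4.

    The male line runs great-grandsires -> grandsires -> sires; training
    animals and Group 1 candidates are offspring of the same sires; Group 2
    candidates' sires are other sons of the training grandsires; Group 3
    candidates' paternal grandsires are other sons of the training
    great-grandsires; Group 4 descends from a disjoint founder line.

    Returns ``(pedigree, roles)`` where roles maps 'training' and
    'group1'..'group4' to id arrays.
    """
    rng = np.random.default_rng(seed)
    animal, sire, dam, sex, gen = [], [], [], [], []
    nid = [0]

    def add(s, d, sx, g):
        nid[0] += 1
        animal.append(nid[0])
        sire.append(s)
        dam.append(d)
        sex.append(sx)
        gen.append(g)
        return nid[0]

    # founder dams per generation tier, one shared pool per line
    def dams_pool(g, line_n):
        return [add(0, 0, "F", g) for _ in range(line_n)]

    # explicit male-line chains: training sire i <- grandsire i <- great-
    # grandsire i, with Group 2/3 sires branching off the right tier
    ggs = [add(0, 0, "M", 0) for _ in range(n_sires)]  # great-grandsires
    d0 = dams_pool(0, n_dams_per_line)
    gs = [add(g, rng.choice(d0), "M", 1) for g in ggs]  # training grandsires
    gs_extra = [add(g, rng.choice(d0), "M", 1) for g in ggs]  # brothers of gs
    d1 = dams_pool(1, n_dams_per_line)
    sires_main = [add(g, rng.choice(d1), "M", 2) for g in gs]
    sires_g2 = [add(g, rng.choice(d1), "M", 2) for g in gs]  # share grandsire
    sires_g3 = [add(g, rng.choice(d1), "M", 2) for g in gs_extra]  # share ggs only
    d2 = dams_pool(2, n_dams_per_line)

    def family(sires_, n_each, g=3):
        out = []
        for s in sires_:
            for _ in range(n_each):
                out.append(add(s, rng.choice(d2), "F", g))
        return np.array(out)

    training = family(sires_main, n_per_family)
    group1 = family(sires_main, n_per_family // 2)
    group2 = family(sires_g2, n_per_family // 2)
    group3 = family(sires_g3, n_per_family // 2)

    # disjoint immigrant line for Group 4
    f_m = [add(0, 0, "M", 0) for _ in range(n_sires)]
    f_f = dams_pool(0, n_dams_per_line)
    m1 = [add(rng.choice(f_m), rng.choice(f_f), "M", 1) for _ in range(n_sires)]
    f1 = dams_pool(1, n_dams_per_line // 2)
    m2 = [add(rng.choice(m1), rng.choice(f1), "M", 2) for _ in range(n_sires)]
    f2 = dams_pool(2, n_dams_per_line // 2)
    group4 = np.array(
        [add(rng.choice(m2), rng.choice(f2), "F", 3) for _ in range(n_sires * (n_per_family // 2))]
    )

    ped = pd.DataFrame(
        {"animal": animal, "sire": sire, "dam": dam, "sex": sex, "generation": gen}
    )
    roles = {
        "training": training,
        "group1": group1,
        "group2": group2,
        "group3": group3,
        "group4": group4,
    }
    return ped, roles
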