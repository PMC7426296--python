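"""Seeded synthetic-data generator with ground truth.

Emulates the statistical structure of an untargeted LC-MS study of wild-type
vs knockout mice (optionally crossed with an antibiotic treatment), plus a
16S taxon table:

* a formula-mass compound database with isomer collisions (a configurable
  fraction of formulas carried by two compounds) and decoy entries that pad
  the mass axis;
* peaks whose best-match mass errors are a mixture of a tight Gaussian true
  component and a broad uniform false component spanning the capture window;
* log-normal peak areas with multiplicative technical-replicate noise,
  genotype fold-change effects, and suppression of bacterial-origin compounds
  under antibiotic treatment;
* Dirichlet-sampled taxon compositions with genus-level concentration shifts
  in the knockout group.

Every sub-generator draws from its own stream spawned from the master seed,
so outputs are reproducible under a fixed seed regardless of call order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import chemmass
from .chemmass import CompoundDatabase, get_adduct, mz_from_neutral
from .peaktable import PeakTable, validate_design
from .taxa import RANKS, TaxonTable

log = logging.getLogger(__name__)

__all__ = [
    "GroupEffect",
    "SimConfig",
    "make_design",
    "simulate_database",
    "simulate_peaks",
    "simulate_taxa",
    "write_dataset",
]

_CLASSES = (
    "tryptophan metabolism",
    "acylcarnitines",
    "lipids",
    "glycine conjugates",
    "others",
)
_CLASS_WEIGHTS = (0.10, 0.15, 0.25, 0.05, 0.45)


@dataclass(frozen=True)
class GroupEffect:
    """A multiplicative group effect on one compound or one compound class."""

    target: str
    by: str = "compound"  # "compound" | "class"
    factor: str = "genotype"
    level: str = "KO"
    fold_change: float = 1.0

    def __post_init__(self) -> None:
        if self.by not in ("compound", "class"):
            raise ValueError("GroupEffect.by must be 'compound' or 'class'")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


@dataclass
class SimConfig:
    """Study conditions for the synthetic datasets.

    Defaults mirror the emulated study design: six biological and three
    technical replicates per genotype, 20% technical CV, a 60/40 split of
    true vs spurious best matches with a 2 ppm true error and a +/-50 ppm
    null, one standard-verified compound ("glutarate") spiked 11-fold in the
    knockout, a tenth of compounds of bacterial origin suppressed 100-fold by
    antibiotics, and 7 vs 7 stool samples for the taxon table.
    """

    seed: int = 1
    # database
    n_compounds: int = 500
    isomer_fraction: float = 0.1
    n_decoy_db_entries: int = 1500
    n_standards: int = 10
    bacterial_fraction: float = 0.1
    mass_range: Tuple[float, float] = (80.0, 1000.0)
    #: minimum pairwise formula-mass separation; > 2x null_error_range keeps
    #: every seeded peak's source entry its unique nearest formula, so ground
    #: truth is exact (see the methods note on this idealization)
    min_formula_separation_ppm: float = 120.0
    # peaks
    n_peaks: int = 2000
    true_match_fraction: float = 0.6  # pi1
    true_error_sd: float = 2.0  # ppm
    null_error_range: float = 50.0  # ppm, half-width of the uniform null
    polarity: str = "positive"
    adducts: Tuple[str, ...] = ("[M+H]+",)
    rt_range: Tuple[float, float] = (2.0, 13.0)
    rt_out_fraction: float = 0.02
    low_height_fraction: float = 0.02
    area_log_mean: float = 14.0
    area_log_sd: float = 1.2
    # design and noise
    organ: str = "kidney"
    treatments: Tuple[str, ...] = ("none",)
    n_bio_replicates: int = 6
    n_tech_replicates: int = 3
    tech_cv: float = 0.2
    group_effects: Tuple[GroupEffect, ...] = (
        GroupEffect("glutarate", "compound", "genotype", "KO", 11.0),
    )
    abx_suppression_factor: float = 100.0
    # taxa
    n_taxa: int = 60
    taxa_concentration: float = 100.0
    taxa_samples_per_group: int = 7
    shifted_genera: Tuple[Tuple[str, float], ...] = (
        ("Genus01", 2.0),
        ("Genus02", 1.5),
        ("Genus03", 0.5),
    )

    def __post_init__(self) -> None:
        for name in ("isomer_fraction", "true_match_fraction", "bacterial_fraction",
                     "rt_out_fraction", "low_height_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.true_error_sd <= 0 or self.null_error_range <= 0:
            raise ValueError("error scales must be positive")
        if self.tech_cv <= 0:
            raise ValueError("tech_cv must be positive")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")

    def _stream(self, which: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[which])


def make_design(cfg: SimConfig) -> pd.DataFrame:
    """Full factorial sample design: genotype x treatment x bio x tech."""
    rows = []
    for genotype in ("WT", "KO"):
        for treatment in cfg.treatments:
            for b in range(1, cfg.n_bio_replicates + 1):
                bio = f"{genotype}_{treatment}_b{b}"
                for t in range(1, cfg.n_tech_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{bio}_t{t}",
                            "genotype": genotype,
                            "treatment": treatment,
                            "biological_replicate": bio,
                            "technical_replicate": f"t{t}",
                            "organ": cfg.organ,
                        }
                    )
    return validate_design(pd.DataFrame(rows))


_EL = {e: chemmass.MONOISOTOPIC_MASSES[e] for e in ("C", "H", "N", "O", "P", "S")}


def _random_formulas(
    rng: np.random.Generator,
    n: int,
    mass_range,
    exclude=(),
    min_sep_ppm: float = 0.0,
    reserved_masses: Sequence[float] = (),
):
    """Distinct plausible CHNOPS formulas with masses inside ``mass_range``.

    With ``min_sep_ppm`` > 0, every accepted formula mass keeps at least that
    relative distance from all previously accepted (and reserved) masses, so
    the mass axis has no near-isobaric formula pairs.
    """
    import bisect

    lo, hi = mass_range
    found: Dict[str, float] = {}
    excluded = set(exclude)
    accepted_masses = sorted(float(m) for m in reserved_masses)

    def _separated(m: float) -> bool:
        if min_sep_ppm <= 0 or not accepted_masses:
            return True
        j = bisect.bisect_left(accepted_masses, m)
        for neighbor in accepted_masses[max(0, j - 1): j + 1]:
            if abs(m - neighbor) / neighbor * 1e6 < min_sep_ppm:
                return False
        return True

    while len(found) < n:
        k = max(64, 2 * (n - len(found)))
        C = rng.integers(2, 45, k)
        H = (C * rng.uniform(1.0, 2.2, k)).astype(int) + rng.integers(0, 3, k)
        N = rng.integers(0, 5, k)
        O = rng.integers(0, 12, k)
        P = rng.integers(0, 3, k)
        S = rng.integers(0, 3, k)
        mass = (
            C * _EL["C"] + H * _EL["H"] + N * _EL["N"]
            + O * _EL["O"] + P * _EL["P"] + S * _EL["S"]
        )
        ok = (mass >= lo) & (mass <= hi)
        for c, h, nn, o, p, s, m in zip(C[ok], H[ok], N[ok], O[ok], P[ok], S[ok], mass[ok]):
            parts = [f"C{c}", f"H{h}"]
            for sym, cnt in (("N", nn), ("O", o), ("P", p), ("S", s)):
                if cnt:
                    parts.append(f"{sym}{cnt}" if cnt > 1 else sym)
            formula = "".join(parts)
            if formula not in found and formula not in excluded and _separated(float(m)):
                found[formula] = float(m)
                if min_sep_ppm > 0:
                    bisect.insort(accepted_masses, float(m))
                if len(found) == n:
                    break
    return list(found.items())


def simulate_database(cfg: SimConfig) -> CompoundDatabase:
    """Generate the compound database: real compounds, isomer pairs, decoys.

    Exactly ``floor(n_compounds * isomer_fraction)`` formulas carry two
    compounds.  The first compound is always "glutarate" (C5H8O4), flagged as
    a standard so the spiked effect is identified with full confidence.
    Decoys pad the mass axis; they are flagged in an ``is_decoy`` column and
    never emit true peaks.
    """
    rng = cfg._stream(0)
    glutarate_formula = "C5H8O4"
    n_random = cfg.n_compounds - 1
    formulas = _random_formulas(
        rng,
        n_random + cfg.n_decoy_db_entries,
        cfg.mass_range,
        exclude=(glutarate_formula,),
        min_sep_ppm=cfg.min_formula_separation_ppm,
        reserved_masses=(chemmass.monoisotopic_mass(glutarate_formula),),
    )
    real = formulas[:n_random]
    decoys = formulas[n_random:]

    classes = list(rng.choice(_CLASSES, size=n_random, p=_CLASS_WEIGHTS))
    bacterial = rng.random(n_random) < cfg.bacterial_fraction
    rows = [
        {
            "compound_id": "CPD0000",
            "name": "glutarate",
            "formula": glutarate_formula,
            "neutral_mass": chemmass.monoisotopic_mass(glutarate_formula),
            "class_label": "others",
            "is_standard": True,
            "is_decoy": False,
        }
    ]
    for i, (formula, mass) in enumerate(real, start=1):
        rows.append(
            {
                "compound_id": f"CPD{i:04d}",
                "name": f"compound-{i:04d}",
                "formula": formula,
                "neutral_mass": mass,
                "class_label": "bacterial origin" if bacterial[i - 1] else classes[i - 1],
                "is_standard": i < cfg.n_standards,  # glutarate is the first standard
                "is_decoy": False,
            }
        )
    n_isomer = int(np.floor(cfg.n_compounds * cfg.isomer_fraction))
    iso_rows = []
    if n_isomer:
        # standards are chosen for being unambiguous; their formulas are kept
        # free of isomer collisions
        eligible = np.array([k for k, r in enumerate(rows) if not r["is_standard"]])
        picks = eligible[rng.choice(len(eligible), size=n_isomer, replace=False)]
        for j, pick in enumerate(sorted(picks)):
            src = rows[pick]
            iso_rows.append(
                {
                    **src,
                    "compound_id": f"ISO{j:04d}",
                    "name": src["name"] + "-isomer",
                    "is_standard": False,
                }
            )
    decoy_rows = [
        {
            "compound_id": f"DCY{i:04d}",
            "name": f"decoy-{i:04d}",
            "formula": formula,
            "neutral_mass": mass,
            "class_label": "others",
            "is_standard": False,
            "is_decoy": True,
        }
        for i, (formula, mass) in enumerate(decoys)
    ]
    frame = pd.DataFrame(rows + iso_rows + decoy_rows)
    return CompoundDatabase.from_frame(frame)


def _effect_multiplier(
    cfg: SimConfig,
    compound_id: Optional[str],
    compound_name: Optional[str],
    class_label: Optional[str],
    design_row: pd.Series,
) -> float:
    mult = 1.0
    if compound_id is None:
        return mult
    for eff in cfg.group_effects:
        hit = (eff.by == "compound" and eff.target in (compound_id, compound_name)) or (
            eff.by == "class" and class_label == eff.target
        )
        if hit and design_row[eff.factor] == eff.level:
            mult *= eff.fold_change
    if class_label == "bacterial origin" and design_row["treatment"] == "abx":
        mult /= cfg.abx_suppression_factor
    return mult


def simulate_peaks(
    cfg: SimConfig, db: CompoundDatabase, design: pd.DataFrame
) -> Tuple[PeakTable, pd.DataFrame]:
    """Generate the peak table and its ground truth.

    A fraction ``true_match_fraction`` of peaks carry the ionized mass of a
    real (non-decoy) database compound perturbed by N(0, true_error_sd) ppm;
    the rest sit at a uniform offset within +/- null_error_range ppm of a
    random database entry, so their best match is spurious but observable
    inside the capture window.  Areas are log-normal with group effects at
    the biological level and multiplicative technical noise; antibiotic
    treatment suppresses bacterial-origin compounds.
    """
    rng = cfg._stream(1)
    design = validate_design(design)
    frame = db.frame
    real_idx = np.flatnonzero(~frame["is_decoy"].to_numpy()) if "is_decoy" in frame else np.arange(len(frame))
    all_masses = frame["neutral_mass"].to_numpy()
    adducts = [get_adduct(name) for name in cfg.adducts]
    if any(a.polarity != cfg.polarity for a in adducts):
        raise ValueError("configured adducts do not match configured polarity")

    n = cfg.n_peaks
    is_true = rng.random(n) < cfg.true_match_fraction
    adduct_pick = rng.integers(0, len(adducts), n)
    comp_pick = rng.choice(real_idx, size=n)
    # Spurious peaks are seeded around non-standard entries: a spurious
    # feature within a few ppm of a verified standard's mass would be
    # indistinguishable from the standard itself, making its ground truth
    # ill-defined.
    non_standard = np.flatnonzero(~frame["is_standard"].to_numpy())
    entry_pick = non_standard[rng.integers(0, len(non_standard), n)]

    # Every compound carrying an explicit effect gets one guaranteed,
    # filter-surviving peak (as a targeted panel compound would); without it a
    # spiked effect could be unobservable by sampling accident.
    ids = frame["compound_id"].to_numpy()
    names = frame["name"].to_numpy()
    pinned = []
    true_indices = np.flatnonzero(is_true)
    for t_i, eff in enumerate([e for e in cfg.group_effects if e.by == "compound"]):
        hit = np.flatnonzero((ids == eff.target) | (names == eff.target))
        if len(hit) == 0:
            raise ValueError(
                f"group effect targets unknown compound {eff.target!r}"
            )
        if t_i >= len(true_indices):
            raise ValueError("too few true peaks to place all group effects")
        comp_pick[true_indices[t_i]] = hit[0]
        pinned.append(true_indices[t_i])
    pinned = np.array(pinned, dtype=int)
    err_true = rng.normal(0.0, cfg.true_error_sd, n)
    err_null = rng.uniform(-cfg.null_error_range, cfg.null_error_range, n)

    # Guarantee the generator's contract: the seeded entry IS the realized
    # nearest database formula, so true best-match errors are exactly
    # N(0, true_error_sd) and spurious ones exactly U(+/- null_error_range).
    # Rejection: redraw a peak whose perturbed mass drifts closer (in ppm) to
    # a different formula mass than to its seeded entry.
    formula_masses = np.unique(all_masses)
    err = np.where(is_true, err_true, err_null)
    src = np.where(is_true, comp_pick, entry_pick)
    for _ in range(100):
        neutral = all_masses[src] * (1.0 + err * 1e-6)
        pos = np.clip(np.searchsorted(formula_masses, neutral), 1, len(formula_masses) - 1)
        lo, hi = formula_masses[pos - 1], formula_masses[pos]
        near = np.where(neutral - lo < hi - neutral, lo, hi)
        d_near = np.abs(neutral - near) / near * 1e6
        d_src = np.abs(neutral - all_masses[src]) / all_masses[src] * 1e6
        bad = (d_near < d_src) & ~np.isclose(near, all_masses[src])
        if len(pinned):
            bad[pinned] = False
        if not bad.any():
            break
        k = int(bad.sum())
        err[bad] = np.where(
            is_true[bad],
            rng.normal(0.0, cfg.true_error_sd, k),
            rng.uniform(-cfg.null_error_range, cfg.null_error_range, k),
        )
        src[bad] = np.where(
            is_true[bad], rng.choice(real_idx, size=k), rng.integers(0, len(frame), k)
        )
    err_true = np.where(is_true, err, err_true)
    err_null = np.where(~is_true, err, err_null)
    comp_pick = np.where(is_true, src, comp_pick)
    neutral = all_masses[src] * (1.0 + err * 1e-6)
    mz = np.array(
        [mz_from_neutral(m, adducts[a]) for m, a in zip(neutral, adduct_pick)]
    )
    rt = rng.uniform(*cfg.rt_range, n)
    out_rt = rng.random(n) < cfg.rt_out_fraction
    if len(pinned):
        out_rt[pinned] = False
    rt[out_rt] = np.where(
        rng.random(out_rt.sum()) < 0.5,
        rng.uniform(0.3, cfg.rt_range[0] - 1e-3, out_rt.sum()),
        rng.uniform(cfg.rt_range[1] + 1e-3, 15.0, out_rt.sum()),
    )
    height = rng.lognormal(np.log(2.0e4), 1.0, n) + 1001.0
    low = rng.random(n) < cfg.low_height_fraction
    if len(pinned):
        low[pinned] = False
    height[low] = rng.uniform(100.0, 1000.0, low.sum())

    base = rng.lognormal(cfg.area_log_mean, cfg.area_log_sd, n)
    sigma_t = np.sqrt(np.log1p(cfg.tech_cv**2))
    comp_ids = ids
    comp_names = names
    comp_classes = frame["class_label"].to_numpy()
    areas = np.empty((n, len(design)))
    group_mult: Dict[Tuple[str, str], np.ndarray] = {}
    for j, (_, srow) in enumerate(design.iterrows()):
        key = (srow["genotype"], srow["treatment"])
        if key not in group_mult:
            group_mult[key] = np.array(
                [
                    _effect_multiplier(
                        cfg,
                        comp_ids[comp_pick[i]] if is_true[i] else None,
                        comp_names[comp_pick[i]] if is_true[i] else None,
                        comp_classes[comp_pick[i]] if is_true[i] else None,
                        srow,
                    )
                    for i in range(n)
                ]
            )
        noise = rng.lognormal(-0.5 * sigma_t**2, sigma_t, n)
        areas[:, j] = base * group_mult[key] * noise

    peak_ids = [f"P{i:06d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "mz": mz,
            "rt": rt,
            "polarity": cfg.polarity,
            "height": height,
        },
        index=pd.Index(peak_ids, name="peak_id"),
    )
    area_frame = pd.DataFrame(
        areas, index=meta.index, columns=list(design["sample_id"])
    )
    truth = pd.DataFrame(
        {
            "peak_id": peak_ids,
            "is_true": is_true,
            "compound_id": np.where(is_true, comp_ids[comp_pick], ""),
            "formula": np.where(is_true, frame["formula"].to_numpy()[comp_pick], ""),
            "class_label": np.where(is_true, comp_classes[comp_pick], ""),
            "adduct": [adducts[a].name for a in adduct_pick],
            "seeded_ppm_error": np.where(is_true, err_true, err_null),
        }
    )
    return PeakTable(meta, area_frame), truth


def _taxonomy_paths(n_taxa: int) -> list:
    """Synthetic 7-rank taxonomy over 4 phyla, 8 families, 16 genera."""
    paths = []
    for i in range(n_taxa):
        genus = i % 16
        family = genus // 2
        phylum = family // 2
        parts = (
            "Bacteria",
            f"Phylum{phylum + 1:02d}",
            f"Class{phylum + 1:02d}",
            f"Order{family + 1:02d}",
            f"Family{family + 1:02d}",
            f"Genus{genus + 1:02d}",
            f"Species{i + 1:03d}",
        )
        paths.append(";".join(parts))
    return paths


def simulate_taxa(cfg: SimConfig) -> Tuple[TaxonTable, pd.DataFrame]:
    """Dirichlet taxon compositions with genus-level shifts in the KO group."""
    if cfg.n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = cfg._stream(2)
    paths = _taxonomy_paths(cfg.n_taxa)
    genera = [p.split(";")[5] for p in paths]
    base = rng.lognormal(0.0, 1.0, cfg.n_taxa)
    base = base / base.sum() * cfg.taxa_concentration
    shift = dict(cfg.shifted_genera)
    alpha_ko = base * np.array([shift.get(g, 1.0) for g in genera])
    rows = []
    cols = {}
    for genotype, alpha in (("WT", base), ("KO", alpha_ko)):
        for s in range(1, cfg.taxa_samples_per_group + 1):
            sid = f"stool_{genotype}_{s}"
            cols[sid] = rng.dirichlet(alpha)
            rows.append({"sample_id": sid, "genotype": genotype})
    table = TaxonTable(pd.DataFrame(cols, index=pd.Index(paths, name="taxonomy")))
    return table, pd.DataFrame(rows)


def write_dataset(cfg: SimConfig, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Write database, design, peaks, ground truth and taxon tables to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = simulate_database(cfg)
    design = make_design(cfg)
    peaks, truth = simulate_peaks(cfg, db, design)
    taxa_table, taxa_design = simulate_taxa(cfg)
    paths = {
        "database": outdir / "database.tsv",
        "design": outdir / "design.tsv",
        "peaks": outdir / "peaks.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "taxa": outdir / "taxa.tsv",
        "taxa_design": outdir / "taxa_design.tsv",
    }
    db.to_csv(paths["database"])
    design.to_csv(paths["design"], sep="\t", index=False)
    peaks.to_csv(paths["peaks"])
    truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    taxa_table.to_csv(paths["taxa"])
    taxa_design.to_csv(paths["taxa_design"], sep="\t", index=False)
    log.info("wrote synthetic dataset (seed %d) to %s", cfg.seed, outdir)
    return paths
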