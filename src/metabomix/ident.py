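"""Compound identification by mass-error mixture deconvolution.

Each extracted peak is queried against a formula-mass database under every
allowed adduct/charge hypothesis, producing a signed ppm error to its nearest
database formula (the *best match*) and to the nearest *distinct* formula (the
*second-best match*).  Best-match errors are a mixture: a tight component from
correct identifications and a broad component from chance matches.  Because
second-best matches are almost surely wrong, their error distribution is an
empirical stand-in for the false component ``f0``.  Holding ``f0`` fixed (a
kernel density over second-best errors, truncated to the modeled error
domain), expectation-maximization fits the true-component weight ``pi1`` and a
Gaussian true component ``f1``, and each peak receives a posterior probability
of true identification

    P(true | e) = pi1 * f1(e) / (pi1 * f1(e) + (1 - pi1) * f0(e)).

Peaks matched to isotopically verified standards bypass the statistical model
and are identified with full confidence.  Assignments are made at formula
level: a posterior at or above the threshold with a unique compound for the
formula is accepted; formulas shared by two or more database compounds are
removed as ambiguous isomers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .chemmass import AdductSpecies, CompoundDatabase, adducts_for_polarity, neutral_mass_from_mz
from .peaktable import PeakTable

log = logging.getLogger(__name__)

__all__ = [
    "Candidate",
    "MatchResult",
    "ErrorMixtureModel",
    "Identification",
    "match_candidates",
    "fit_error_mixture",
    "compute_posteriors",
    "assign_identifications",
    "identification_frame",
    "AnnotationResult",
    "annotate",
]

#: Candidate-search window for best-match eligibility, ppm.  Wide enough that
#: the mixture sees chance matches well beyond the ~20 ppm of accepted
#: identifications; second-best matches are recorded without any window.
DEFAULT_CAPTURE_WINDOW_PPM = 50.0
#: Window for standard-based identification, ppm.  Standards are externally
#: verified compounds; a hit is only credited to a standard at the extraction
#: mass tolerance, not over the whole statistical capture window.
DEFAULT_STANDARD_WINDOW_PPM = 10.0


@dataclass(frozen=True)
class Candidate:
    """One database formula considered for a peak under one adduct."""

    compound_ids: Tuple[str, ...]
    formula: str
    adduct: str
    ppm_error: float
    theoretical_mass: float
    observed_neutral_mass: float


@dataclass
class MatchResult:
    """Best and second-best (distinct-formula) database matches for one peak."""

    peak_id: str
    best: Optional[Candidate]
    second_best: Optional[Candidate]
    is_standard_match: bool = False

    def __post_init__(self) -> None:
        if self.best is not None and self.second_best is not None:
            if abs(self.best.ppm_error) > abs(self.second_best.ppm_error) + 1e-9:
                raise ValueError("best match must have the smaller |ppm error|")


def match_candidates(
    peaks: PeakTable,
    db: CompoundDatabase,
    adducts: Optional[Sequence[AdductSpecies]] = None,
    capture_window_ppm: float = DEFAULT_CAPTURE_WINDOW_PPM,
    standard_window_ppm: float = DEFAULT_STANDARD_WINDOW_PPM,
) -> List[MatchResult]:
    """Match every peak against the database under all adduct hypotheses.

    For each peak, every (adduct, charge) hypothesis yields a neutral-mass
    guess; the minimum-|error| database formula over all hypotheses is the
    best match (eligible only within ``capture_window_ppm``), and the
    minimum-|error| formula distinct from it is the second-best match,
    recorded without a window so it can populate the false-match null.  Ties
    in |error| are broken by database order (logged).
    """
    if len(db) == 0:
        raise ValueError("empty compound database")
    ft = db.formula_table()
    masses = ft["neutral_mass"].to_numpy()
    db_order = ft["db_order"].to_numpy()
    k = len(masses)
    results: List[MatchResult] = []
    offsets = np.array([-2, -1, 0, 1])

    for polarity, meta in peaks.meta.groupby("polarity", sort=False):
        if adducts is None:
            adds = adducts_for_polarity(polarity)
        else:
            adds = [a for a in adducts if a.polarity == polarity]
        if not adds:
            raise ValueError(f"no adducts available for polarity {polarity!r}")
        mz = meta["mz"].to_numpy(dtype=float)
        n = len(mz)
        err_blocks, idx_blocks, obs_blocks, add_names = [], [], [], []
        for a in adds:
            observed = neutral_mass_from_mz(mz, a)
            pos = np.searchsorted(masses, observed)
            idx = pos[:, None] + offsets[None, :]
            valid = (idx >= 0) & (idx < k)
            cidx = np.clip(idx, 0, k - 1)
            err = (observed[:, None] - masses[cidx]) / masses[cidx] * 1e6
            err[~valid] = np.inf
            err_blocks.append(err)
            idx_blocks.append(cidx)
            obs_blocks.append(np.broadcast_to(observed[:, None], err.shape))
            add_names.extend([a.name] * len(offsets))
        E = np.hstack(err_blocks)
        I = np.hstack(idx_blocks)
        OBS = np.hstack([np.asarray(b) for b in obs_blocks])

        for i, peak_id in enumerate(meta.index):
            row_err = E[i]
            finite = np.isfinite(row_err)
            if not finite.any():
                results.append(MatchResult(peak_id, None, None, False))
                continue
            cols = np.nonzero(finite)[0]
            # sort by |error| with database order as deterministic tie-break
            order = np.lexsort((db_order[I[i, cols]], np.abs(row_err[cols])))
            cols = cols[order]
            if len(cols) > 1 and np.isclose(
                abs(row_err[cols[0]]), abs(row_err[cols[1]]), rtol=0, atol=1e-12
            ):
                log.debug(
                    "peak %s: nearest-match tie broken by database order", peak_id
                )

            def _cand(col: int) -> Candidate:
                j = I[i, col]
                return Candidate(
                    compound_ids=ft["compound_ids"].iat[j],
                    formula=ft["formula"].iat[j],
                    adduct=add_names[col],
                    ppm_error=float(row_err[col]),
                    theoretical_mass=float(masses[j]),
                    observed_neutral_mass=float(OBS[i, col]),
                )

            best_col = cols[0]
            best_formula = ft["formula"].iat[I[i, best_col]]
            second: Optional[Candidate] = None
            for col in cols[1:]:
                if ft["formula"].iat[I[i, col]] != best_formula:
                    second = _cand(col)
                    break
            within = abs(row_err[best_col]) <= capture_window_ppm
            best = _cand(best_col) if within else None
            is_standard = bool(
                abs(row_err[best_col]) <= standard_window_ppm
                and ft["standard_ids"].iat[I[i, best_col]]
            )
            results.append(MatchResult(peak_id, best, second, is_standard))
    return results


@dataclass
class ErrorMixtureModel:
    """Fitted two-component mixture over signed ppm best-match errors.

    ``f1`` is a Gaussian (location ``mu1``, scale ``sigma1``) truncated to the
    modeled domain ``[-domain_ppm, +domain_ppm]``; ``f0`` is a fixed kernel
    density estimated from second-best errors, renormalized over the same
    domain.  Both densities integrate to 1 over the domain.
    """

    pi1: float
    mu1: float
    sigma1: float
    domain_ppm: float
    grid: np.ndarray = field(repr=False)
    f0_grid: np.ndarray = field(repr=False)
    n_peaks: int = 0
    n_iter: int = 0
    log_likelihood: float = float("nan")
    converged: bool = False
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError(f"pi1 must lie in [0, 1], got {self.pi1}")

    def f0(self, e):
        e = np.asarray(e, dtype=float)
        out = np.interp(e, self.grid, self.f0_grid, left=0.0, right=0.0)
        return out

    def f1(self, e):
        e = np.asarray(e, dtype=float)
        w = self.domain_ppm
        norm = stats.norm(self.mu1, self.sigma1)
        trunc = norm.cdf(w) - norm.cdf(-w)
        out = np.where(np.abs(e) <= w, norm.pdf(e) / trunc, 0.0)
        return out

    def posterior(self, e):
        """P(true identification | signed ppm error e)."""
        num = self.pi1 * self.f1(e)
        den = num + (1.0 - self.pi1) * self.f0(e)
        with np.errstate(invalid="ignore"):
            post = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        if np.any(den <= 0):
            log.warning(
                "posterior undefined (both densities vanish) for %d error value(s); "
                "returning 0",
                int(np.sum(den <= 0)),
            )
        return post

    def check_normalization(self, rtol: float = 1e-3) -> bool:
        a0 = np.trapezoid(self.f0_grid, self.grid)
        a1 = np.trapezoid(self.f1(self.grid), self.grid)
        return bool(abs(a0 - 1) < rtol and abs(a1 - 1) < rtol)


def fit_error_mixture(
    matches: Sequence[MatchResult],
    min_matches: int = 50,
    domain_ppm: float = DEFAULT_CAPTURE_WINDOW_PPM,
    max_iter: int = 500,
    tol: float = 1e-8,
    error_mode: str = "signed",
    fitted_on: str = "",
) -> ErrorMixtureModel:
    """Deconvolve best-match errors into true and false components.

    The false density ``f0`` is a Gaussian kernel density over the signed
    second-best errors of all peaks (Silverman rule-of-thumb bandwidth),
    truncated and renormalized over ``[-domain_ppm, +domain_ppm]`` and held
    fixed.  EM then maximizes the likelihood of
    ``pi1 * f1(e) + (1 - pi1) * f0(e)`` over the best-match errors inside the
    domain, with deterministic initialization (pi1 = 0.5, mu1 = 0, sigma1 =
    median |e|) and convergence when the log-likelihood changes by < ``tol``.

    Standard-matched peaks bypass the model and are excluded from the fit.

    ``error_mode="absolute"`` discards the sign information: errors are
    folded to |e| and mirrored, which pins the true component at zero and
    forces both densities symmetric (use when the mass axis is known to be
    well calibrated).
    """
    if error_mode not in ("signed", "absolute"):
        raise ValueError(f"error_mode must be signed|absolute, got {error_mode!r}")
    e_best = np.array(
        [
            m.best.ppm_error
            for m in matches
            if m.best is not None and m.second_best is not None and not m.is_standard_match
        ]
    )
    e_second = np.array(
        [m.second_best.ppm_error for m in matches if m.second_best is not None]
    )
    e_best = e_best[np.abs(e_best) <= domain_ppm]
    n_fit = len(e_best)
    if n_fit < min_matches:
        raise ValueError(
            f"too few matches to fit the mixture: {n_fit} < {min_matches}"
        )
    if error_mode == "absolute":
        e_best = np.concatenate([np.abs(e_best), -np.abs(e_best)])
        e_second = np.concatenate([np.abs(e_second), -np.abs(e_second)])
    if np.ptp(e_second) == 0:
        raise ValueError("degenerate null: all second-best errors are identical")

    kde = stats.gaussian_kde(e_second, bw_method="silverman")
    grid = np.linspace(-domain_ppm, domain_ppm, 2001)
    f0_grid = kde(grid)
    area = np.trapezoid(f0_grid, grid)
    if area <= 0:
        raise ValueError("null density has no mass inside the modeled domain")
    f0_grid = f0_grid / area
    f0_at = np.interp(e_best, grid, f0_grid)

    pi1 = 0.5
    mu1 = 0.0
    sigma1 = max(float(np.median(np.abs(e_best))), 0.05)
    ll_prev = -np.inf
    n_iter = 0
    converged = False
    w = domain_ppm
    for n_iter in range(1, max_iter + 1):
        norm = stats.norm(mu1, sigma1)
        trunc = max(norm.cdf(w) - norm.cdf(-w), 1e-12)
        f1_at = norm.pdf(e_best) / trunc
        num = pi1 * f1_at
        den = num + (1.0 - pi1) * f0_at
        den = np.maximum(den, 1e-300)
        resp = num / den
        pi1 = float(np.mean(resp))
        rsum = max(resp.sum(), 1e-12)
        mu1 = float(np.dot(resp, e_best) / rsum)
        sigma1 = float(np.sqrt(np.dot(resp, (e_best - mu1) ** 2) / rsum))
        sigma1 = max(sigma1, 0.05)
        ll = float(np.sum(np.log(den)))
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    model = ErrorMixtureModel(
        pi1=min(max(pi1, 0.0), 1.0),
        mu1=mu1,
        sigma1=sigma1,
        domain_ppm=domain_ppm,
        grid=grid,
        f0_grid=f0_grid,
        n_peaks=n_fit,
        n_iter=n_iter,
        log_likelihood=ll,
        converged=converged,
        fitted_on=fitted_on,
    )
    log.info(
        "mixture fit (%s): pi1=%.3f mu1=%.2f ppm sigma1=%.2f ppm on %d peaks "
        "(%d EM iterations)",
        fitted_on or "unstratified",
        model.pi1,
        model.mu1,
        model.sigma1,
        model.n_peaks,
        n_iter,
    )
    return model


def compute_posteriors(
    model: ErrorMixtureModel, matches: Sequence[MatchResult]
) -> Dict[str, float]:
    """Posterior probability of true identification for each matched peak.

    Standard-matched peaks are excluded (they bypass the model; the
    assignment stage gives them posterior 1).
    """
    out: Dict[str, float] = {}
    for m in matches:
        if m.best is None or m.is_standard_match:
            continue
        out[m.peak_id] = float(model.posterior(m.best.ppm_error))
    return out


@dataclass
class Identification:
    """Final identification call for one peak, at formula level."""

    peak_id: str
    compound_ids: Tuple[str, ...]
    formula: str
    adduct: str
    ppm_error: float
    posterior: float
    status: str  # standard | assigned | ambiguous_isomer_removed | unassigned

    def __post_init__(self) -> None:
        if self.status == "standard" and self.posterior != 1.0:
            raise ValueError("standard identifications carry posterior 1")


def assign_identifications(
    matches: Sequence[MatchResult],
    posteriors: Dict[str, float],
    db: CompoundDatabase,
    threshold: float = 0.8,
) -> Tuple[List[Identification], Dict[str, float]]:
    """Apply the assignment rules and summarize.

    Standards are identified with full confidence.  Otherwise a posterior at
    or above ``threshold`` yields an assignment when the matched formula maps
    to a single database compound; formulas carried by two or more compounds
    are removed as ambiguous isomers.  Everything else is unassigned.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"posterior threshold must lie in (0, 1], got {threshold}")
    idents: List[Identification] = []
    for m in matches:
        if m.best is None:
            idents.append(
                Identification(m.peak_id, (), "", "", float("nan"), 0.0, "unassigned")
            )
            continue
        b = m.best
        if m.is_standard_match:
            ft = db.formula_table()
            std_ids = ft.loc[ft["formula"] == b.formula, "standard_ids"].iat[0]
            idents.append(
                Identification(
                    m.peak_id, tuple(std_ids), b.formula, b.adduct, b.ppm_error, 1.0, "standard"
                )
            )
            continue
        post = posteriors.get(m.peak_id, 0.0)
        if post >= threshold:
            status = "assigned" if len(b.compound_ids) == 1 else "ambiguous_isomer_removed"
        else:
            status = "unassigned"
        idents.append(
            Identification(
                m.peak_id, b.compound_ids, b.formula, b.adduct, b.ppm_error, post, status
            )
        )
    accepted = [i for i in idents if i.status in ("standard", "assigned")]
    counts = pd.Series([i.status for i in idents]).value_counts().to_dict()
    summary = {
        "n_peaks": float(len(idents)),
        "n_identified": float(len(accepted)),
        "fraction_assigned": len(accepted) / len(idents) if idents else 0.0,
        "max_abs_ppm_assigned": max(
            (abs(i.ppm_error) for i in accepted), default=float("nan")
        ),
        **{f"n_{k}": float(v) for k, v in counts.items()},
    }
    return idents, summary


def identification_frame(idents: Sequence[Identification]) -> pd.DataFrame:
    """Tabulate identifications for delimited-text output."""
    return pd.DataFrame(
        {
            "peak_id": [i.peak_id for i in idents],
            "compound_id": [";".join(i.compound_ids) for i in idents],
            "formula": [i.formula for i in idents],
            "adduct": [i.adduct for i in idents],
            "ppm_error": [i.ppm_error for i in idents],
            "posterior": [i.posterior for i in idents],
            "status": [i.status for i in idents],
        }
    )


@dataclass
class AnnotationResult:
    matches: List[MatchResult]
    model: ErrorMixtureModel
    posteriors: Dict[str, float]
    identifications: List[Identification]
    summary: Dict[str, float]


def annotate(
    peaks: PeakTable,
    db: CompoundDatabase,
    adducts: Optional[Sequence[AdductSpecies]] = None,
    capture_window_ppm: float = DEFAULT_CAPTURE_WINDOW_PPM,
    threshold: float = 0.8,
    min_matches: int = 50,
    standard_window_ppm: float = DEFAULT_STANDARD_WINDOW_PPM,
    error_mode: str = "signed",
    fitted_on: str = "",
) -> AnnotationResult:
    """Run matching, mixture fitting, posteriors and assignment for one stratum.

    One stratum is one (organ, polarity) slice of the data; positive- and
    negative-mode tables must be annotated separately.
    """
    matches = match_candidates(peaks, db, adducts, capture_window_ppm, standard_window_ppm)
    model = fit_error_mixture(
        matches,
        min_matches=min_matches,
        domain_ppm=capture_window_ppm,
        error_mode=error_mode,
        fitted_on=fitted_on,
    )
    posteriors = compute_posteriors(model, matches)
    idents, summary = assign_identifications(matches, posteriors, db, threshold)
    return AnnotationResult(matches, model, posteriors, idents, summary)
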