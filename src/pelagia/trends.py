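"""Day-to-day activity-budget trend models and the quasi-flightless summary.

The response of interest is the proportion of each bird-day spent in a given
activity (sustained flight, floating, active foraging) as a smooth function
of days since colony departure (DSD), with non-breeding phase and species as
fixed factors, a per-bird random intercept, and exponentially decaying
temporal correlation between days of the same bird. Daily flight time is
zero-inflated, so it is modelled as a two-stage hurdle: a binary model for
whether any sustained flight occurred and a quasi-binomial model for the
positive proportions.

The fitter is a penalized-spline GAMM estimated by penalized quasi-likelihood
(PQL): iteratively reweighted working responses are fitted by generalized
least squares with a per-bird covariance
``V_b = sigma_b^2 J + phi * W^(-1/2) C_b(range) W^(-1/2)`` where
``C_b[i,j] = exp(-|dsd_i - dsd_j| / range)``, smoothing parameters are
chosen per smooth term by Gaussian REML on the whitened working model, and
the variance components are updated by method of moments from working
residuals. Term significance uses Wald-type F statistics with
smoothing-adjusted degrees of freedom (edf from the hat matrix; the species
main effect, a between-bird contrast, is tested against bird-level
replication); backward selection removes the least significant droppable
term at a time until all retained terms are significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.interpolate import BSpline

__all__ = [
    "ActivityTrendModel", "TrendResults", "HurdleTrendResults",
    "build_activity_panel", "quasiflightless_summary", "QuasiFlightlessSummary",
]

PANEL_COLUMNS = ["bird_id", "species", "dsd", "phase", "flight_prop",
                 "float_prop", "forage_prop", "flight_any", "daily_km"]


def build_activity_panel(budgets: pd.DataFrame, records: dict,
                         species: dict, daily_km: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Assemble the bird-day modelling panel from daily budgets.

    ``budgets`` is the concatenated :func:`pelagia.immersion.daily_budget`
    output; ``records`` maps bird_id -> PhenologyRecord; ``species`` maps
    bird_id -> species code. Rows outside [departure, return] are dropped and
    DSD/phase assigned from each bird's record. ``daily_km`` (bird_id, date,
    daily_km) is merged if given.
    """
    rows = []
    for bird, rec in records.items():
        b = budgets[budgets["bird_id"] == bird].copy()
        if b.empty:
            continue
        b["dsd"] = rec.dsd(b["date"])
        b["phase"] = rec.phase_of(b["date"])
        b = b[b["phase"] != ""]
        b["species"] = species[bird]
        rows.append(b)
    panel = pd.concat(rows, ignore_index=True)
    panel["flight_any"] = (panel["flight_prop"] > 0).astype(int)
    if daily_km is not None:
        panel = panel.merge(daily_km[["bird_id", "date", "daily_km"]],
                            on=["bird_id", "date"], how="left")
    elif "daily_km" not in panel:
        panel["daily_km"] = np.nan
    return panel


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _bspline_design(x, knots_inner, degree=3):
    lo, hi = knots_inner[0], knots_inner[-1]
    t = np.concatenate([[lo] * degree, knots_inner, [hi] * degree])
    return BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()


def _second_diff_penalty(k):
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


@dataclass
class _Term:
    name: str
    cols: slice
    penalized: bool
    droppable: bool
    requires: tuple = ()
    pen: np.ndarray | None = None   # penalty matrix for this block


class _Design:
    """Full design matrix with named, droppable term blocks."""

    def __init__(self, panel: pd.DataFrame, k: int = 10,
                 by_species_smooth: bool = True, include_phase: bool = True,
                 include_species: bool = True, include_interaction: bool = True):
        self.k = k
        dsd = panel["dsd"].values.astype(float)
        qs = np.linspace(0, 100, k - 2)
        knots = np.unique(np.percentile(dsd, qs))
        if len(knots) < 4:
            raise ValueError("too few distinct dsd values for a smooth")
        self.knots = knots
        self.degree = 3
        b_raw = _bspline_design(dsd, knots, self.degree)
        self.basis_means = b_raw.mean(axis=0)
        self.pen_k = _second_diff_penalty(self.n_basis)
        # deviation smooths are re-expressed in the penalty's positive
        # eigenspace (null space removed): they carry only *nonlinear* shape
        # differences, so constant/linear species effects cannot leak into
        # them and inflate the term's apparent significance
        vals, vecs = np.linalg.eigh(self.pen_k)
        keep = vals > 1e-8 * vals.max()
        self.dev_transform = vecs[:, keep] / np.sqrt(vals[keep])
        self.species_levels = sorted(panel["species"].unique())
        self.phase_levels = ["outbound", "overwinter", "inbound"]
        self.two_species = len(self.species_levels) > 1

        self.include = {
            "phase": include_phase,
            "species": include_species and self.two_species,
            "phase:species": include_interaction and include_phase
            and include_species and self.two_species,
            "s(dsd):species": by_species_smooth and self.two_species,
        }
        self.X, self.terms = self._build(panel)

    def _blocks(self, panel):
        dsd = panel["dsd"].values.astype(float)
        b = _bspline_design(dsd, self.knots, self.degree) - self.basis_means
        blocks = [("intercept", np.ones((len(panel), 1)), False, False, (), None)]
        blocks.append(("s(dsd)", b, True, False, (), self.pen_k))
        if self.include["s(dsd):species"]:
            ind = (panel["species"].values == self.species_levels[1]).astype(float)
            dev = (b * ind[:, None]) @ self.dev_transform
            blocks.append(("s(dsd):species", dev, True, True, (),
                           np.eye(dev.shape[1])))
        if self.include["phase"]:
            ph = np.column_stack([
                (panel["phase"].values == lev).astype(float)
                for lev in self.phase_levels[1:]])
            blocks.append(("phase", ph, False, True, (), None))
        if self.include["species"]:
            sp = (panel["species"].values == self.species_levels[1]).astype(float)
            blocks.append(("species", sp[:, None], False, True, (), None))
        if self.include["phase:species"]:
            ph = np.column_stack([
                (panel["phase"].values == lev).astype(float)
                for lev in self.phase_levels[1:]])
            sp = (panel["species"].values == self.species_levels[1]).astype(float)
            blocks.append(("phase:species", ph * sp[:, None], False, True,
                           ("phase", "species"), None))
        return blocks

    def _build(self, panel):
        mats, terms, start = [], [], 0
        for name, m, penalized, drop, req, pen in self._blocks(panel):
            if not self.include.get(name, True):
                continue
            terms.append(_Term(name, slice(start, start + m.shape[1]),
                               penalized, drop, req, pen))
            mats.append(m)
            start += m.shape[1]
        return np.column_stack(mats), terms

    def matrix_for(self, panel):
        """Design matrix for new rows under the current term set."""
        mats = []
        for name, m, *_ in self._blocks(panel):
            if self.include.get(name, True) and any(t.name == name for t in self.terms):
                mats.append(m)
        return np.column_stack(mats)

    def drop(self, name):
        self.include[name] = False

    @property
    def n_basis(self):
        return len(self.knots) + self.degree - 1


# ---------------------------------------------------------------------------
# PQL fitting engine
# ---------------------------------------------------------------------------

def _corexp_chol(dsd_b, rng_par):
    c = np.exp(-np.abs(dsd_b[:, None] - dsd_b[None, :]) / rng_par)
    return c


def _whiten(X, z, w, bird_codes, dsd, sigma_b2, phi, corr_range):
    """Per-bird GLS whitening: returns L^-1 X and L^-1 z stacked."""
    Xw = np.empty_like(X)
    zw = np.empty_like(z)
    for b in np.unique(bird_codes):
        m = bird_codes == b
        dinv = 1.0 / np.sqrt(w[m])
        if corr_range is not None:
            c = _corexp_chol(dsd[m], corr_range)
        else:
            c = np.eye(m.sum())
        v = sigma_b2 + phi * (dinv[:, None] * c * dinv[None, :])
        v[np.diag_indices_from(v)] += 1e-8
        ell = linalg.cholesky(v, lower=True)
        Xw[m] = linalg.solve_triangular(ell, X[m], lower=True)
        zw[m] = linalg.solve_triangular(ell, z[m], lower=True)
    return Xw, zw


def _pql_fit(design: _Design, y, bird_ids, dsd, family="quasibinomial",
             use_re=True, use_corr=True, max_outer=12,
             lam_grid=None, tol=1e-4):
    X = design.X
    n, p = X.shape
    if lam_grid is None:
        lam_grid = np.logspace(-2, 5, 12)
    codes = pd.factorize(bird_ids)[0]
    y = np.asarray(y, dtype=float)
    mu = np.clip(0.9 * y + 0.05, 1e-4, 1 - 1e-4)
    eta = np.log(mu / (1 - mu))
    phi, sigma_b2, corr_range = 1.0, 0.0, None
    beta = np.zeros(p)

    pen_terms = [t for t in design.terms if t.penalized]
    lam_best = tuple(lam_grid[len(lam_grid) // 2] for _ in pen_terms)
    A = None

    def penalty_multi(lams):
        s = np.zeros((p, p))
        for t, lam in zip(pen_terms, lams):
            s[t.cols, t.cols] += lam * t.pen
        s[np.diag_indices_from(s)] += 1e-8
        return s

    import itertools
    lam_candidates = list(itertools.product(lam_grid, repeat=len(pen_terms))) \
        if pen_terms else [()]

    for it in range(max_outer):
        w = np.clip(mu * (1 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        Xw, zw = _whiten(X, z, w, codes, dsd.astype(float),
                         sigma_b2 if use_re else 0.0, phi,
                         corr_range if use_corr else None)
        xtx = Xw.T @ Xw
        xtz = Xw.T @ zw
        # smoothing parameters by Gaussian REML on the whitened working model
        # (REML is much more resistant than GCV to undersmoothing into
        # group-labelled noise); constants independent of lambda dropped
        ranks = [int(np.linalg.matrix_rank(t.pen)) for t in pen_terms]
        m0 = p - sum(ranks)
        best = None
        for lams in lam_candidates:
            a = xtx + penalty_multi(lams)
            try:
                beta_l = linalg.solve(a, xtz, assume_a="pos")
            except linalg.LinAlgError:
                continue
            s_pen = penalty_multi(lams)
            rss_pen = float(((zw - Xw @ beta_l) ** 2).sum()
                            + beta_l @ s_pen @ beta_l)
            sign, logdet_a = np.linalg.slogdet(a)
            if sign <= 0:
                continue
            reml = ((n - m0) * np.log(max(rss_pen, 1e-300)) + logdet_a
                    - sum(r * np.log(lam) for r, lam in zip(ranks, lams)))
            if best is None or reml < best[0]:
                edf = np.trace(linalg.solve(a, xtx, assume_a="pos"))
                best = (reml, lams, beta_l, edf, a)
        _, lam_best, beta_new, edf, A = best
        eta_new = np.clip(X @ beta_new, -15, 15)
        delta = np.max(np.abs(eta_new - eta)) if it else np.inf
        eta, beta = eta_new, beta_new
        mu = 1.0 / (1.0 + np.exp(-eta))

        # variance-component updates from working residuals
        e = z - X @ beta
        r = e * np.sqrt(w)
        if family == "quasibinomial":
            phi = max(float((r ** 2).sum() / max(n - edf, 1.0)), 1e-3)
        else:
            phi = 1.0
        if use_re:
            mb = pd.Series(e).groupby(codes).mean()
            nb = pd.Series(e).groupby(codes).size()
            noise = pd.Series(phi / w).groupby(codes).mean() / nb
            sigma_b2 = float(max(mb.var(ddof=1) - noise.mean(), 0.0))
        if use_corr:
            eb = e - mb.values[codes] if use_re else e
            u = eb * np.sqrt(w)
            lag = pd.DataFrame({"b": codes, "d": dsd, "u": u}).sort_values(["b", "d"])
            u1, u0 = lag["u"].values[1:], lag["u"].values[:-1]
            ok = (np.diff(lag["d"].values) == 1) & (np.diff(lag["b"].values) == 0)
            if ok.sum() > 20:
                rho1 = float(np.corrcoef(u0[ok], u1[ok])[0, 1])
            else:
                rho1 = 0.0
            corr_range = (-1.0 / np.log(rho1) if 0.02 < rho1 < 0.95 else None)
        if delta < tol:
            break

    # V (hence the whitened design) already carries phi, so the Bayesian
    # coefficient covariance in whitened coordinates is A^-1 itself
    cov = linalg.inv(A)
    # per-term effective degrees of freedom from the hat-type matrix
    h_diag = np.diag(linalg.solve(A, Xw.T @ Xw, assume_a="pos"))
    return {
        "beta": beta, "cov": cov, "phi": phi, "sigma_b2": sigma_b2,
        "corr_range": corr_range, "lam": lam_best, "edf_total": float(h_diag.sum()),
        "edf_diag": h_diag, "mu": mu, "eta": eta, "n": n,
        "n_birds": int(codes.max()) + 1,
    }


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ActivityTrendModel:
    """GAMM for one activity response over days since departure.

    Parameters
    ----------
    panel : bird-day frame with at least bird_id, species, dsd, phase and the
        response columns (see :data:`PANEL_COLUMNS`).
    response : 'float', 'forage', or 'flight_hurdle' (two-stage hurdle for
        the zero-inflated daily flight proportion).
    k : spline basis dimension for the DSD smooth (penalized, so k is an
        upper bound on wiggliness, not a df choice).
    by_species_smooth : include a penalized species-deviation smooth so each
        species can have its own DSD trend; the deviation is droppable by
        backward selection.
    """

    RESPONSES = ("float", "forage", "flight_hurdle")

    def __init__(self, panel: pd.DataFrame, response: str, k: int = 10,
                 by_species_smooth: bool = True, use_random_intercept: bool = True,
                 use_temporal_corr: bool = True,
                 exclude_phase_truncated: tuple = ()):
        if response not in self.RESPONSES:
            raise ValueError(f"response must be one of {self.RESPONSES}")
        p = panel.copy()
        if exclude_phase_truncated:
            # birds with equinox-truncated phases: keep for full-season smooths,
            # drop from phase-level contrasts by masking their phase factor
            p = p[~p["bird_id"].isin(exclude_phase_truncated)
                  | (p["phase"] == "overwinter")]
        if p["bird_id"].nunique() < 2:
            raise ValueError("panel needs >= 2 birds")
        if len(p) < 50:
            raise ValueError("panel needs >= 50 bird-days")
        for col in ("flight_prop", "float_prop", "forage_prop"):
            if not np.isfinite(p[col]).all():
                raise ValueError(f"non-finite values in {col}")
        self.panel = p.reset_index(drop=True)
        self.response = response
        self.k = k
        self.by_species_smooth = by_species_smooth
        self.use_re = use_random_intercept
        self.use_corr = use_temporal_corr

    # -- single-stage fit with backward selection ---------------------------

    def _fit_one(self, sub: pd.DataFrame, y, family, alpha, select):
        design = _Design(sub, k=self.k, by_species_smooth=self.by_species_smooth)
        trace = []
        step = 0
        while True:
            fit = _pql_fit(design, y, sub["bird_id"].values, sub["dsd"].values,
                           family=family, use_re=self.use_re,
                           use_corr=self.use_corr)
            table = self._term_table(design, fit)
            if not select:
                break
            blocked = {r for t in design.terms for r in t.requires}
            cand = table[table["droppable"] & ~table["term"].isin(blocked)]
            worst = cand.sort_values("p", ascending=False).head(1)
            if worst.empty or worst["p"].iloc[0] <= alpha:
                break
            name = worst["term"].iloc[0]
            trace.append({"step": step, "dropped": name,
                          "F": float(worst["F"].iloc[0]),
                          "p": float(worst["p"].iloc[0])})
            design.drop(name)
            design.X, design.terms = design._build(sub)
            step += 1
            if step > 10:
                break
        return TrendResults(response=self.response, design=design, fit=fit,
                            term_table=table.drop(columns="droppable"),
                            selection_trace=trace, panel=sub, alpha=alpha)

    @staticmethod
    def _term_table(design, fit):
        rows = []
        beta, cov = fit["beta"], fit["cov"]
        n = fit["n"]
        den_df = max(n - fit["edf_total"], 1.0)
        # a species main effect is a between-bird contrast: its effective
        # replication is the number of birds, not the number of bird-days
        den_between = max(fit.get("n_birds", 2) - 2, 1.0)
        for t in design.terms:
            if t.name == "intercept":
                continue
            b = beta[t.cols]
            v = cov[t.cols, t.cols]
            edf = float(fit["edf_diag"][t.cols].sum()) if t.penalized \
                else float(b.size)
            try:
                stat = float(b @ linalg.solve(v, b, assume_a="pos"))
            except linalg.LinAlgError:
                stat = float(b @ np.linalg.pinv(v) @ b)
            # df floored at 1: a term shrunk toward edf 0 carries ~no signal
            # and must not manufacture significance through a tiny divisor
            test_df = max(edf, 1.0)
            f = stat / test_df
            den = den_between if t.name == "species" else den_df
            pval = float(stats.f.sf(f, test_df, den))
            rows.append({"term": t.name, "df": edf, "F": f, "p": pval,
                         "droppable": t.droppable})
        return pd.DataFrame(rows)

    def fit(self, alpha: float = 0.05, select: bool = True):
        """Fit (and backward-select) the model.

        Returns :class:`TrendResults`, or :class:`HurdleTrendResults` with
        independent binary and positive-part stages for ``flight_hurdle``.
        """
        p = self.panel
        if self.response in ("float", "forage"):
            y = np.clip(p[f"{self.response}_prop"].values, 1e-6, 1 - 1e-6)
            return self._fit_one(p, y, "quasibinomial", alpha, select)
        # hurdle
        y_bin = p["flight_any"].values.astype(float)
        binary = self._fit_one(p, y_bin, "binomial", alpha, select)
        pos = p[p["flight_prop"] > 0].reset_index(drop=True)
        diagnostics = []
        positive = None
        if len(pos) >= 50 and pos["bird_id"].nunique() >= 2:
            y_pos = np.clip(pos["flight_prop"].values, 1e-6, 1 - 1e-6)
            positive = self._fit_one(pos, y_pos, "quasibinomial", alpha, select)
        else:
            diagnostics.append(
                f"positive-part stage skipped: only {len(pos)} flight-positive "
                "bird-days")
        return HurdleTrendResults(binary=binary, positive=positive,
                                  diagnostics=diagnostics)


@dataclass
class TrendResults:
    """One fitted trend model: estimates, tests, smooths, selection trace."""

    response: str
    design: _Design
    fit: dict
    term_table: pd.DataFrame
    selection_trace: list
    panel: pd.DataFrame
    alpha: float

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fitted mean proportions (response scale) for the fitting panel."""
        return self.fit["mu"]

    @property
    def phi(self):
        return self.fit["phi"]

    @property
    def sigma_b2(self):
        return self.fit["sigma_b2"]

    @property
    def corr_range(self):
        return self.fit["corr_range"]

    def predict(self, panel: pd.DataFrame) -> np.ndarray:
        """Population-level (random intercept = 0) fitted proportions."""
        x = self.design.matrix_for(panel)
        return 1.0 / (1.0 + np.exp(-np.clip(x @ self.fit["beta"], -15, 15)))

    def smooth_frame(self, species: str | None = None, n_grid: int = 200,
                     phase: str = "overwinter") -> pd.DataFrame:
        """DSD grid with the fitted smooth (link scale) and 95% CI band."""
        dsd = np.linspace(self.panel["dsd"].min(), self.panel["dsd"].max(), n_grid)
        if species is None:
            species = self.design.species_levels[0]
        grid = pd.DataFrame({"dsd": dsd, "species": species, "phase": phase})
        x = self.design.matrix_for(grid)
        eta = x @ self.fit["beta"]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", x, self.fit["cov"], x), 0))
        return pd.DataFrame({"dsd": dsd, "eta": eta,
                             "eta_lo": eta - 1.96 * se, "eta_hi": eta + 1.96 * se,
                             "prop": 1 / (1 + np.exp(-eta))})

    def summary(self) -> str:
        lines = [f"Activity trend model: {self.response}",
                 f"  n bird-days = {self.fit['n']}, total edf = "
                 f"{self.fit['edf_total']:.2f}, scale phi = {self.phi:.3f}",
                 f"  random-intercept variance = {self.sigma_b2:.4f}, "
                 f"corExp range = "
                 + (f"{self.corr_range:.2f} d" if self.corr_range else "none"),
                 "  term                    df       F        P"]
        for _, r in self.term_table.iterrows():
            lines.append(f"  {r['term']:<22s}{r['df']:>6.2f}{r['F']:>9.2f}"
                         f"{r['p']:>10.2g}")
        for s in self.selection_trace:
            lines.append(f"  dropped '{s['dropped']}' (F={s['F']:.2f}, "
                         f"p={s['p']:.3f}) at step {s['step']}")
        return "\n".join(lines)

    def has_term(self, name: str) -> bool:
        return any(t.name == name for t in self.design.terms)


@dataclass
class HurdleTrendResults:
    """Two-stage hurdle fit for the zero-inflated daily flight proportion."""

    binary: TrendResults
    positive: TrendResults | None
    diagnostics: list = field(default_factory=list)

    def expected_flight(self, panel: pd.DataFrame) -> np.ndarray:
        """E[proportion] = P(flight) x E[proportion | flight > 0]."""
        p_any = self.binary.predict(panel)
        if self.positive is None:
            return p_any * np.nan
        return p_any * self.positive.predict(panel)

    def summary(self) -> str:
        parts = ["Hurdle model for daily sustained flight",
                 "--- stage 1: flight yes/no (binary) ---",
                 self.binary.summary()]
        if self.positive is not None:
            parts += ["--- stage 2: proportion | flight > 0 (quasi-binomial) ---",
                      self.positive.summary()]
        parts += self.diagnostics
        return "\n".join(parts)


# ---------------------------------------------------------------------------
# Quasi-flightless summary
# ---------------------------------------------------------------------------

@dataclass
class QuasiFlightlessSummary:
    """Counts of flightless/float-dominated days inside a DSD window."""

    window: tuple
    per_bird: pd.DataFrame
    cohort: pd.DataFrame

    def summary(self) -> str:
        lines = [f"Quasi-flightless window: DSD {self.window[0]}-{self.window[1]}"]
        for _, r in self.cohort.iterrows():
            lines.append(
                f"  {r['species']}: zero-flight days {r['zero_flight_mean']:.1f} "
                f"+/- {r['zero_flight_sd']:.1f}; all-float days "
                f"{r['all_float_mean']:.1f} +/- {r['all_float_sd']:.1f}; "
                f">90% float {r['float_gt90_mean']:.1f} +/- {r['float_gt90_sd']:.1f}; "
                f">80% float {r['float_gt80_mean']:.1f} +/- {r['float_gt80_sd']:.1f}; "
                f"daily km {r['daily_km_mean']:.0f}")
        return "\n".join(lines)


def quasiflightless_summary(panel: pd.DataFrame, window=(30, 70)) -> QuasiFlightlessSummary:
    """Per-bird and cohort counts of quasi-flightless behaviour.

    Inside the DSD window, counts per bird: days with no sustained flight,
    days spent entirely floating (floating fills all non-excluded time),
    days floating >80% and >90% of the day (strict thresholds), plus the mean
    daily travel distance. Cohort rows give mean ± SD per species.
    """
    lo, hi = window
    if panel["dsd"].max() < lo or panel["dsd"].min() > hi:
        import warnings
        warnings.warn("quasi-flightless window outside observed DSD range; "
                      "summary is empty")
        empty = pd.DataFrame()
        return QuasiFlightlessSummary(window=window, per_bird=empty, cohort=empty)
    w = panel[(panel["dsd"] >= lo) & (panel["dsd"] <= hi)].copy()
    if "excluded_min" in w:
        all_float = (1440.0 * (1.0 - w["float_prop"]) - w["excluded_min"]) < 1e-6
    else:
        all_float = w["float_prop"] >= 0.999
    w["_zero_flight"] = w["flight_prop"] == 0
    w["_all_float"] = all_float
    w["_gt80"] = w["float_prop"] > 0.80
    w["_gt90"] = w["float_prop"] > 0.90
    per_bird = w.groupby(["species", "bird_id"]).agg(
        n_days=("dsd", "size"),
        zero_flight_days=("_zero_flight", "sum"),
        all_float_days=("_all_float", "sum"),
        float_gt80_days=("_gt80", "sum"),
        float_gt90_days=("_gt90", "sum"),
        mean_daily_km=("daily_km", "mean"),
    ).reset_index()
    agg = {}
    for col, out in [("zero_flight_days", "zero_flight"),
                     ("all_float_days", "all_float"),
                     ("float_gt80_days", "float_gt80"),
                     ("float_gt90_days", "float_gt90")]:
        agg[f"{out}_mean"] = (col, "mean")
        agg[f"{out}_sd"] = (col, lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
    agg["daily_km_mean"] = ("mean_daily_km", "mean")
    agg["n_birds"] = ("bird_id", "size")
    cohort = per_bird.groupby("species").agg(**agg).reset_index()
    return QuasiFlightlessSummary(window=window, per_bird=per_bird, cohort=cohort)
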