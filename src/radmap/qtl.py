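"""Composite interval mapping (CIM) for doubled-haploid populations.

The scan is Haley-Knott-style regression on expected genotype scores: DH
genotypes are coded +1 (parent A) / -1 (parent B) at markers, and between
markers the expectation is computed from the flanking calls through Haldane
no-interference conditional probabilities. At each grid position (1-cM walk
by default) the line-mean trait is regressed on that expectation plus
background marker cofactors, excluding any cofactor within a 50-cM window
of the position; the likelihood-ratio statistic of the nested comparison,
LR = n*ln(RSS0/RSS1), is reported as LOD = 0.217*LR, the convention used by
QTL Cartographer.

Cofactors (up to 7) come from forward-selection backward-elimination
stepwise regression at significance 0.1, one candidate per co-segregation
bin. Experiment-wise thresholds come from trait permutations (default 1000,
alpha = 0.05); the entire analysis -- cofactor selection included -- is
repeated on every permuted trait, so the genome-wide maximum LOD of the
observed data is exchangeable with the permuted ones under the null and the
threshold is calibrated despite the selection step.

Also here: broad-sense heritability from replicated trait data,
H2 = sG2/(sG2 + se2/r), and the derived trait GY = SN*GN*HGW.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import MISSING
from .linkage import haldane_inverse

logger = logging.getLogger(__name__)

LOD_PER_LR = 0.217  # reporting convention; exact 1/(2 ln 10) = 0.2171...
MAX_COFACTORS = 7
COFACTOR_ALPHA = 0.1
WINDOW_CM = 50.0
STEP_CM = 1.0
N_PERM = 1000
PERM_ALPHA = 0.05

_TINY = 1e-12


# ------------------------------------------------------------------ traits

def trait_means(traits: pd.DataFrame) -> pd.DataFrame:
    """Genotype (line) means: individuals x traits, NaN-aware."""
    return traits.pivot_table(index="individual", columns="trait",
                              values="value", aggfunc="mean")


def derive_gy(traits: pd.DataFrame) -> pd.DataFrame:
    """Append grain yield GY = SN*GN*HGW, computed on genotype means.

    Spike number (SN), grain number per spike (GN) and hundred grain
    weight (HGW, g) must be present; any missing component leaves GY
    missing for that individual. The formula is applied literally (HGW is
    not divided by 100), so GY is on the scale the formula defines.
    """
    means = trait_means(traits)
    for comp in ("SN", "GN", "HGW"):
        if comp not in means.columns:
            raise ValueError(f"trait {comp} required to derive GY")
    gy = means["SN"] * means["GN"] * means["HGW"]
    rows = [(ind, "GY", 1, val) for ind, val in gy.items()]
    extra = pd.DataFrame(rows, columns=["individual", "trait", "replicate",
                                        "value"])
    return pd.concat([traits, extra], ignore_index=True)


@dataclass
class HeritabilityEstimate:
    trait: str
    sigma_g2: float
    sigma_e2: float
    n_reps: int

    @property
    def h2(self) -> float:
        denom = self.sigma_g2 + self.sigma_e2 / self.n_reps
        return self.sigma_g2 / denom if denom > 0 else 0.0


def estimate_heritability(traits: pd.DataFrame) -> dict[str, HeritabilityEstimate]:
    """One-way random-effects variance decomposition per trait.

    se2 is the within-genotype mean square, sG2 = max(0, (between-MS -
    within-MS)/r) with r replicates per genotype, and H2 = sG2/(sG2 +
    se2/r). Requires at least 2 replicates per genotype.
    """
    out = {}
    for trait, sub in traits.dropna(subset=["value"]).groupby("trait"):
        groups = [g["value"].to_numpy() for _, g in sub.groupby("individual")]
        if min(len(g) for g in groups) < 2:
            raise ValueError(f"trait {trait}: need >= 2 replicates per genotype")
        n_g = len(groups)
        grand = np.concatenate(groups).mean()
        means = np.array([g.mean() for g in groups])
        sizes = np.array([len(g) for g in groups])
        ms_between = float((sizes * (means - grand) ** 2).sum() / (n_g - 1))
        ms_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups)
                          / (sizes - 1).sum())
        r_eff = float(sizes.mean())
        sigma_g2 = max(0.0, (ms_between - ms_within) / r_eff)
        out[trait] = HeritabilityEstimate(trait, sigma_g2, ms_within,
                                          int(round(r_eff)))
    return out


# ------------------------------------------------- genotype expectations

def _score_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Markers x individuals scores: A=+1, B=-1, missing=0 (1:1 mean)."""
    return ((matrix == "A").to_numpy(dtype=float)
            - (matrix == "B").to_numpy(dtype=float))


def genotype_expectation(gmap: pd.DataFrame, matrix: pd.DataFrame,
                         step_cM: float = STEP_CM
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Expected +-1 genotype score at every grid position.

    The grid covers each linkage group from 0 to its length in steps of
    ``step_cM``. For an individual with informative flanking calls gL at
    distance dL and gR at dR the conditional expectation follows Haldane
    probabilities (rLR = rL + rR - 2*rL*rR):

        both flanks equal g:     score = g * ((1-rL)(1-rR) - rL*rR) / (1-rLR)
        flanks differ (gL = g):  score = g * ((1-rL)*rR - rL*(1-rR)) / rLR

    With a single informative flank the expectation decays toward 0 as
    g * exp(-2d/100); with none it is 0 (uninformative). Returns
    (grid table with columns group, cM; positions x individuals array).
    """
    n_ind = matrix.shape[1]
    scores = _score_matrix(matrix)
    marker_row = {m: i for i, m in enumerate(matrix.index)}
    grid_rows: list[tuple[str, float]] = []
    blocks: list[np.ndarray] = []
    for group, sub in gmap.groupby("group", sort=False):
        sub = sub.sort_values(["position_cM", "marker"])
        members = [m for m in sub["marker"] if m in marker_row]
        if not members:
            continue
        mpos = sub.set_index("marker")["position_cM"]
        pos = np.array([mpos[m] for m in members])
        length = float(pos.max())
        grid = np.arange(0.0, length + step_cM / 2, step_cM)
        if grid.size == 0 or grid[-1] < length:
            grid = np.append(grid, length)
        rows = np.array([marker_row[m] for m in members])
        g_scores = scores[rows]  # members x individuals, 0 = missing
        block = np.zeros((len(grid), n_ind))
        for j in range(n_ind):
            inf = np.flatnonzero(g_scores[:, j] != 0)
            if inf.size == 0:
                continue
            ipos = pos[inf]
            icall = g_scores[inf, j]
            right_idx = np.searchsorted(ipos, grid, side="left")
            for q, rj in enumerate(right_idx):
                has_l = rj > 0
                has_r = rj < inf.size
                if has_l and has_r:
                    d_l = grid[q] - ipos[rj - 1]
                    d_r = ipos[rj] - grid[q]
                    g_l, g_r = icall[rj - 1], icall[rj]
                    r_l = haldane_inverse(d_l)
                    r_r = haldane_inverse(d_r)
                    r_lr = r_l + r_r - 2.0 * r_l * r_r
                    if g_l == g_r:
                        num = (1 - r_l) * (1 - r_r) - r_l * r_r
                        block[q, j] = g_l * num / (1.0 - r_lr)
                    elif r_lr > 0:
                        num = (1 - r_l) * r_r - r_l * (1 - r_r)
                        block[q, j] = g_l * num / r_lr
                    # contradictory co-located flanks: leave 0
                elif has_l:
                    d = grid[q] - ipos[-1]
                    block[q, j] = icall[-1] * np.exp(-2.0 * d / 100.0)
                else:
                    d = ipos[0] - grid[q]
                    block[q, j] = icall[0] * np.exp(-2.0 * d / 100.0)
        grid_rows += [(group, float(c)) for c in grid]
        blocks.append(block)
    grid_df = pd.DataFrame(grid_rows, columns=["group", "cM"])
    exps = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, n_ind))
    return grid_df, exps


# ------------------------------------------------------------- scan engine

def _orth_basis(X: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of col(X), dropping numerically dependent columns."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > tol * max(float(diag.max(initial=0.0)), 1.0)
    return q[:, keep]


class ScanEngine:
    """Precomputed CIM machinery for one (map, genotype matrix) pair.

    Holds the genome grid, the expected genotype score at every grid
    position, and the candidate-cofactor score matrix (one marker per
    co-segregation bin). Cofactor selection and the LOD profile for an
    arbitrary trait vector and cofactor set are then pure linear algebra,
    fast enough to repeat the full analysis on a thousand permuted traits.
    """

    def __init__(self, gmap: pd.DataFrame, matrix: pd.DataFrame,
                 window_cM: float = WINDOW_CM,
                 step_cM: float = STEP_CM) -> None:
        self.window_cM = window_cM
        self.step_cM = step_cM
        self.grid, self.exps = genotype_expectation(gmap, matrix, step_cM)
        self.n = matrix.shape[1]
        groups, self._grid_group = np.unique(self.grid["group"], return_inverse=True)
        self._group_code = {g: c for c, g in enumerate(groups)}
        self._grid_cm = self.grid["cM"].to_numpy()
        # candidate cofactors: one representative per (group, bin)
        reps = (gmap.sort_values(["group", "bin", "marker"])
                .groupby(["group", "bin"], sort=False)
                .first().reset_index())
        reps = reps[reps["marker"].isin(matrix.index)]
        self.candidates: list[str] = reps["marker"].tolist()
        self._cand_scores = _score_matrix(matrix.loc[self.candidates]).T
        self._cand_group = np.array([self._group_code[g]
                                     for g in reps["group"]])
        self._cand_cm = reps["position_cM"].to_numpy(dtype=float)
        self._cand_index = {m: i for i, m in enumerate(self.candidates)}
        self._ones = np.ones((self.n, 1))

    # ---------------------------------------------------------- selection

    def select_cofactors(self, y: np.ndarray,
                         max_cofactors: int = MAX_COFACTORS,
                         alpha: float = COFACTOR_ALPHA) -> list[str]:
        """Stepwise forward-selection backward-elimination cofactors.

        Forward: add the candidate with the smallest partial-F p-value if
        p < alpha; backward: drop any selected marker with partial-F
        p >= alpha; iterate to a fixed point or max_cofactors markers.
        """
        y = np.asarray(y, dtype=float)
        if len(y) < 10:
            raise ValueError("need trait values for >= 10 individuals")
        if max_cofactors <= 0 or not self.candidates:
            return []
        S = self._cand_scores
        n = self.n
        selected: list[int] = []
        while True:
            changed = False
            if len(selected) < max_cofactors:
                X = np.column_stack([self._ones]
                                    + [S[:, j] for j in selected])
                Q = _orth_basis(X)
                e = y - Q @ (Q.T @ y)
                St = S - Q @ (Q.T @ S)
                d = (St * St).sum(axis=0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    gain = np.where(d > _TINY, (St.T @ e) ** 2 / d, 0.0)
                gain[selected] = 0.0
                rss_red = float(e @ e)
                df2 = n - Q.shape[1] - 1
                if df2 > 0:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        f = gain / np.maximum(rss_red - gain, _TINY) * df2
                    p = stats.f.sf(f, 1, df2)
                    best = int(np.argmin(p))
                    if p[best] < alpha and gain[best] > _TINY:
                        selected.append(best)
                        changed = True
            if len(selected) > 1:
                while len(selected) > 1:
                    X = np.column_stack([self._ones]
                                        + [S[:, j] for j in selected])
                    beta, rss_full, *_ = np.linalg.lstsq(X, y, rcond=None)
                    resid = y - X @ beta
                    rss_full = float(resid @ resid)
                    df2 = n - X.shape[1]
                    if df2 <= 0:
                        break
                    xtx_inv = np.linalg.pinv(X.T @ X)
                    sigma2 = rss_full / df2
                    with np.errstate(divide="ignore", invalid="ignore"):
                        f_drop = beta[1:] ** 2 / np.maximum(
                            sigma2 * np.diag(xtx_inv)[1:], _TINY)
                    p_drop = stats.f.sf(f_drop, 1, df2)
                    worst = int(np.argmax(p_drop))
                    if p_drop[worst] >= alpha:
                        del selected[worst]
                        changed = True
                    else:
                        break
            if not changed or len(selected) >= max_cofactors:
                break
        return [self.candidates[j] for j in selected]

    # --------------------------------------------------------------- scan

    def _position_stats(self, y: np.ndarray, cofactors: list[str]
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lod, additive, qtl_gain) arrays over the grid for one trait.

        Grid positions are grouped by which cofactors fall outside the
        exclusion window; per distinct active set the cofactor-only model
        is orthonormalised once and the QTL term's RSS reduction follows
        from projecting the expectation columns on its complement.
        """
        y = np.asarray(y, dtype=float)
        P = len(self.grid)
        cof_idx = [self._cand_index[m] for m in cofactors]
        if cof_idx:
            cg = self._cand_group[cof_idx]
            cm = self._cand_cm[cof_idx]
            active = ~((cg[None, :] == self._grid_group[:, None])
                       & (np.abs(self._grid_cm[:, None] - cm[None, :])
                          < self.window_cM))
            mask_id = active @ (1 << np.arange(len(cof_idx)))
        else:
            active = np.ones((P, 0), dtype=bool)
            mask_id = np.zeros(P, dtype=int)
        lod = np.zeros(P)
        additive = np.zeros(P)
        gain_out = np.zeros(P)
        cof_scores = self._cand_scores[:, cof_idx] if cof_idx \
            else np.zeros((self.n, 0))
        for mid in np.unique(mask_id):
            idx = np.flatnonzero(mask_id == mid)
            C = cof_scores[:, active[idx[0]]]
            Q = _orth_basis(np.column_stack([self._ones, C]))
            qy = Q.T @ y
            rss0 = max(float(y @ y - qy @ qy), 0.0)
            E = self.exps[idx]                      # p x n
            Et = E - (E @ Q) @ Q.T
            d = (Et * Et).sum(axis=1)
            num = Et @ y
            with np.errstate(divide="ignore", invalid="ignore"):
                gain = np.where(d > _TINY, num ** 2 / d, 0.0)
                beta = np.where(d > _TINY, num / d, 0.0)
            gain = np.minimum(gain, rss0)
            rss1 = rss0 - gain
            if rss0 > _TINY:
                lr = self.n * np.log(rss0 / np.maximum(rss1, _TINY * rss0))
                lod[idx] = LOD_PER_LR * np.maximum(lr, 0.0)
            additive[idx] = beta
            gain_out[idx] = gain
        return lod, additive, gain_out

    def max_lod(self, y: np.ndarray, cofactors: list[str]) -> float:
        lod, _, _ = self._position_stats(y, cofactors)
        return float(lod.max(initial=0.0))


@dataclass
class QtlScan:
    trait: str
    profile: pd.DataFrame      # group, cM, lod, additive, r2
    cofactors: list[str]
    threshold: float | None = None
    qtl: pd.DataFrame | None = None


def select_cofactors(matrix: pd.DataFrame, gmap: pd.DataFrame,
                     y: np.ndarray | pd.Series,
                     max_cofactors: int = MAX_COFACTORS,
                     alpha: float = COFACTOR_ALPHA,
                     engine: ScanEngine | None = None) -> list[str]:
    """Stepwise cofactor selection (see :meth:`ScanEngine.select_cofactors`)."""
    eng = engine or ScanEngine(gmap, matrix)
    return eng.select_cofactors(np.asarray(y, dtype=float),
                                max_cofactors=max_cofactors, alpha=alpha)


def cim_scan(gmap: pd.DataFrame, matrix: pd.DataFrame,
             y: np.ndarray | pd.Series, trait: str = "trait",
             cofactors: list[str] | None = None,
             window_cM: float = WINDOW_CM, step_cM: float = STEP_CM,
             engine: ScanEngine | None = None) -> QtlScan:
    """CIM profile of one trait: LOD, additive effect and R2 per position.

    With no cofactors this reduces exactly to simple interval mapping.
    The additive effect is the regression coefficient on the +-1 score
    (half the fitted contrast between the two genotype classes); R2 is the
    fraction of total trait variance explained by the QTL term beyond the
    cofactor model at that position.
    """
    y = np.asarray(y, dtype=float)
    eng = engine or ScanEngine(gmap, matrix, window_cM, step_cM)
    cof = list(cofactors or [])
    lod, additive, gain = eng._position_stats(y, cof)
    sst = float(((y - y.mean()) ** 2).sum())
    profile = eng.grid.copy()
    profile["lod"] = lod
    profile["additive"] = additive
    profile["r2"] = gain / sst if sst > 0 else 0.0
    return QtlScan(trait, profile, cof)


def permutation_threshold(gmap: pd.DataFrame, matrix: pd.DataFrame,
                          y: np.ndarray | pd.Series,
                          cofactors: list[str] | None = None,
                          n_perm: int = N_PERM, alpha: float = PERM_ALPHA,
                          seed: int | None = None,
                          window_cM: float = WINDOW_CM,
                          step_cM: float = STEP_CM,
                          engine: ScanEngine | None = None,
                          reselect: bool = True,
                          max_cofactors: int = MAX_COFACTORS,
                          cofactor_alpha: float = COFACTOR_ALPHA) -> float:
    """Experiment-wise LOD threshold from trait permutations.

    Trait values are permuted across individuals ``n_perm`` times with a
    fixed seed and the genome-wide maximum LOD recorded per permutation;
    the threshold is the empirical (1-alpha) quantile. By default the full
    analysis, cofactor selection included, is re-run on every permuted
    trait so the observed maximum is exchangeable with the permuted ones
    under the global null; ``reselect=False`` instead freezes the supplied
    cofactors (faster, but anti-conservative after stepwise selection).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: threshold quantile is unstable",
                      stacklevel=2)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    eng = engine or ScanEngine(gmap, matrix, window_cM, step_cM)
    max_lods = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        if reselect:
            cof = eng.select_cofactors(yp, max_cofactors=max_cofactors,
                                       alpha=cofactor_alpha)
        else:
            cof = list(cofactors or [])
        max_lods[b] = eng.max_lod(yp, cof)
    return float(np.quantile(max_lods, 1.0 - alpha))


def support_interval(scan: QtlScan, group: str, peak_cM: float,
                     drop: float = 2.0) -> tuple[float, float]:
    """Widest contiguous interval around the peak with LOD >= peak - drop."""
    prof = scan.profile[scan.profile["group"] == group].reset_index(drop=True)
    idx = int((prof["cM"] - peak_cM).abs().idxmin())
    peak_lod = prof.loc[idx, "lod"]
    lo = idx
    while lo > 0 and prof.loc[lo - 1, "lod"] >= peak_lod - drop:
        lo -= 1
    hi = idx
    while hi < len(prof) - 1 and prof.loc[hi + 1, "lod"] >= peak_lod - drop:
        hi += 1
    return float(prof.loc[lo, "cM"]), float(prof.loc[hi, "cM"])


def declare_qtl(scan: QtlScan, threshold: float, drop: float = 2.0
                ) -> pd.DataFrame:
    """Per-group peaks above the threshold, with 2-LOD support intervals."""
    rows = []
    for group, prof in scan.profile.groupby("group", sort=False):
        prof = prof.reset_index(drop=True)
        i = int(prof["lod"].idxmax())
        if prof.loc[i, "lod"] < threshold:
            continue
        lo, hi = support_interval(scan, group, float(prof.loc[i, "cM"]), drop)
        rows.append((scan.trait, group, float(prof.loc[i, "cM"]), lo, hi,
                     float(prof.loc[i, "lod"]), float(prof.loc[i, "additive"]),
                     float(prof.loc[i, "r2"]), threshold))
    return pd.DataFrame(rows, columns=["trait", "group", "peak_cM",
                                       "ci_lo_cM", "ci_hi_cM", "lod",
                                       "additive", "r2", "threshold"])
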