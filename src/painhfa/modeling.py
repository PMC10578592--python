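"""Sliding-window mixed-effects modeling of pain reports.

For each brain region, trial event and 500 ms window, the mean z-scored
HFA amplitude ``A`` is regressed on the behavioral report with crossed
random intercepts and slopes for stimulus temperature and patient:

    y ~ 1 + A + (1 + A | temperature) + (1 + A | patient)

with a binomial (logit) family for the binary "was that painful?"
response and a gaussian family for the 0-10 graded rating.  Significance
is assessed by a permutation test: responses are shuffled within patient
and the model refit to build a pseudo-t null; the real t is significant
when it falls outside the null's central 95% range, with the two-sided
permutation p-value floored at 2/n_permutations.

The module exposes a statsmodels-style pair: :class:`PainGlme` (model)
and :class:`PainGlmeResults` (estimates + ``summary()`` +
``permutation_test()``), plus thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import MixedGLM, MixedGLMResults
from .preprocess import EpochSet

__all__ = [
    "window_grid",
    "build_features",
    "PainGlme",
    "PainGlmeResults",
    "PermutationResult",
    "fit_glme",
    "permutation_test",
    "pvalue_from_counts",
]

WINDOW_MS = 500.0
STEP_MS = 250.0
DEFAULT_SPANS = {"hand_on": (-250.0, 1000.0), "hand_off": (-1000.0, 1000.0)}
MIN_PERMUTATIONS = 40  # fewer cannot resolve central 95% bounds

FEATURE_COLUMNS = ["patient_id", "trial_id", "temperature", "A",
                   "y_binary", "y_vas"]


def window_grid(event: str | None = None, span=None,
                width: float = WINDOW_MS, step: float = STEP_MS):
    """Half-open 500 ms windows stepping by 250 ms over ``span``.

    Default spans: (-250, 1000) ms around hand-on, (-1000, 1000) ms
    around hand-off.
    """
    if span is None:
        if event not in DEFAULT_SPANS:
            raise ValueError(f"no default span for event {event!r}")
        span = DEFAULT_SPANS[event]
    lo, hi = float(span[0]), float(span[1])
    if hi - lo < width:
        raise ValueError(f"span {span} is shorter than the {width} ms window")
    starts = np.arange(lo, hi - width + 1e-9, step)
    return [(float(s), float(s + width)) for s in starts]


def build_features(
    hfa: EpochSet,
    trial_table: pd.DataFrame,
    channel_idx,
    window,
) -> pd.DataFrame:
    """Per-trial region feature for one patient and one window.

    ``A`` is the mean z-scored envelope over the window samples, then
    over the patient's retained channels among ``channel_idx``; trials
    with no retained channel are dropped.  Returns one row per retained
    trial with the behavioral responses joined on trial id.
    """
    if hfa.units != "z":
        raise ValueError("features require z-scored HFA epochs")
    channel_idx = np.asarray(channel_idx, dtype=int)
    if channel_idx.size == 0:
        raise ValueError("no channels selected")
    start, end = window
    if start < hfa.t_start_ms + hfa.edge_trim_ms - 1e-9:
        raise ValueError(f"window {window} outside the epoch's valid span")
    sl = hfa.time_slice(start, end)
    if sl.stop - sl.start < 1:
        raise ValueError(f"window {window} outside the epoch span")
    t_end = hfa.t_start_ms + hfa.n_times * 1000.0 / hfa.fs
    if end > t_end - hfa.edge_trim_ms + 1e-9:
        raise ValueError(f"window {window} outside the epoch's valid span")
    win_mean = hfa.data[:, channel_idx, sl].mean(axis=-1)  # trials x sel
    keep = ~hfa.reject_mask[:, channel_idx]
    n_keep = keep.sum(axis=1)
    sums = np.where(keep, win_mean, 0.0).sum(axis=1)
    a = np.divide(sums, n_keep, out=np.full(len(sums), np.nan),
                  where=n_keep > 0)
    tt = trial_table.set_index("trial_id")
    rows = []
    for i, tid in enumerate(hfa.trial_ids):
        if not np.isfinite(a[i]):
            continue  # all channels rejected for this trial
        r = tt.loc[int(tid)]
        rows.append(
            dict(
                patient_id=r["patient_id"], trial_id=int(tid),
                temperature=float(r["temperature"]), A=float(a[i]),
                y_binary=int(r["binary_response"]), y_vas=float(r["vas"]),
            )
        )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.attrs["window"] = (float(start), float(end))
    df.attrs["event"] = hfa.event
    return df


def pvalue_from_counts(count_more_extreme: int, n_perm: int = 1000) -> float:
    """Two-sided permutation p-value, floored at 2/n_perm and capped at 1.

    ``count_more_extreme`` is the number of pseudo-t values more extreme
    than the real t in the tail matching its sign.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not 0 <= count_more_extreme <= n_perm:
        raise ValueError(
            f"count {count_more_extreme} outside [0, {n_perm}]"
        )
    return min(1.0, 2.0 * max(count_more_extreme, 1) / n_perm)


@dataclass
class PermutationResult:
    """Pseudo-t null summary for one fitted window model."""

    t_real: float
    pseudo_t: np.ndarray
    bounds: tuple
    p_value: float
    significant: bool
    n_permutations: int
    n_effective: int
    n_nonconverged: int
    unreliable: bool
    family: str
    seed: int | None = None

    def __repr__(self):
        return (
            f"PermutationResult(t_real={self.t_real:.3f}, "
            f"bounds=({self.bounds[0]:.3f}, {self.bounds[1]:.3f}), "
            f"p={self.p_value:.4g}, significant={self.significant}, "
            f"n_eff={self.n_effective})"
        )


class PainGlme:
    """Mixed-effects model of one (region, event, window) feature table.

    Parameters
    ----------
    features : DataFrame
        Output of :func:`build_features` (possibly concatenated over
        patients): columns patient_id, trial_id, temperature, A,
        y_binary, y_vas.
    family : {"binomial", "gaussian"}
        binomial models the binary report; gaussian models the VAS
        rating.
    temp_decimals : int
        Temperatures are rounded to this many decimals to form the
        levels of the temperature grouping factor.
    """

    def __init__(self, features: pd.DataFrame, family: str = "binomial",
                 temp_decimals: int = 1, min_patients: int = 3):
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if len(features) == 0:
            raise ValueError("empty feature table")
        n_pat = features["patient_id"].nunique()
        if n_pat < min_patients:
            raise ValueError(
                f"only {n_pat} patients; at least {min_patients} required"
            )
        y = features["y_binary"] if family == "binomial" else features["y_vas"]
        if family == "binomial" and features["y_binary"].nunique() < 2:
            raise ValueError("binomial model requires both response classes")
        self.features = features.reset_index(drop=True)
        self.family = family
        temp_levels = self.features["temperature"].round(temp_decimals)
        self._glmm = MixedGLM(
            np.asarray(y, dtype=float),
            self.features["A"].to_numpy(dtype=float),
            groups={
                "temperature": pd.factorize(temp_levels)[0],
                "patient": pd.factorize(self.features["patient_id"])[0],
            },
            family=family,
        )
        self._patient_blocks = [
            np.flatnonzero(self.features["patient_id"] == pid)
            for pid in self.features["patient_id"].unique()
        ]

    @classmethod
    def from_dataframe(cls, features, family="binomial", **kw):
        return cls(features, family=family, **kw)

    def fit(self, **kw) -> "PainGlmeResults":
        return PainGlmeResults(self, self._glmm.fit(**kw))

    def _permuted_response(self, rng):
        y = self._glmm.y.copy()
        for block in self._patient_blocks:
            y[block] = y[block[rng.permutation(block.size)]]
        return y


class PainGlmeResults:
    """Fitted window model: estimates, diagnostics, permutation test."""

    def __init__(self, model: PainGlme, res: MixedGLMResults):
        self.model = model
        self._res = res

    # -- statsmodels-flavored surface ---------------------------------- #
    @property
    def beta(self) -> float:
        """Fixed-effect coefficient of mean windowed HFA (A)."""
        return self._res.beta

    @property
    def se_beta(self) -> float:
        return self._res.se_beta

    @property
    def t_stat(self) -> float:
        return self._res.t_stat

    @property
    def params(self):
        return self._res.params

    @property
    def converged(self) -> bool:
        return self._res.converged

    @property
    def separated(self) -> bool:
        return self._res.separated

    @property
    def fitted_conditional(self) -> np.ndarray:
        """Predicted response per trial including random effects
        (probability of "yes" for the binomial family)."""
        return self._res.fitted_conditional

    @property
    def random_effect_sds(self) -> dict:
        return self._res.re_sds

    @property
    def response(self) -> np.ndarray:
        return self.model._glmm.y

    def conf_int(self, alpha: float = 0.05):
        return self._res.conf_int(alpha)

    def summary(self) -> str:
        head = (
            f"PainGlme {self.model.family} model: "
            f"{len(self.model.features)} trials, "
            f"{self.model.features['patient_id'].nunique()} patients\n"
        )
        return head + self._res.summary()

    # -- permutation significance -------------------------------------- #
    def permutation_test(
        self,
        n_perm: int = 1000,
        seed: int | None = None,
        refit_variance: bool = False,
    ) -> PermutationResult:
        """Pseudo-t permutation test of the HFA fixed effect.

        Responses are shuffled within patient (keeping A, temperature and
        patient fixed) and the model refit ``n_perm`` times; fixed
        effects and random-effect modes are re-estimated each time, with
        variance components held at the observed-data estimates unless
        ``refit_variance``.  The real t is significant when outside the
        2.5-97.5 percentile range of the pseudo-t null.  Non-converged
        refits are dropped; the result is marked unreliable if more than
        10% drop.
        """
        if n_perm < MIN_PERMUTATIONS:
            raise ValueError(
                f"n_perm={n_perm} cannot resolve 95% bounds; "
                f"need >= {MIN_PERMUTATIONS}"
            )
        rng = np.random.default_rng(seed)
        glmm = self.model._glmm
        theta = self._res.theta
        pseudo = np.empty(n_perm)
        bad = 0
        for k in range(n_perm):
            y_perm = self.model._permuted_response(rng)
            if refit_variance:
                r = MixedGLM(
                    y_perm, glmm.a,
                    {n: glmm._codes[n] for n in glmm.factor_names},
                    family=glmm.family,
                ).fit(start_theta=theta, maxfev=120)
            else:
                r = glmm.refit_responses(y_perm, theta)
            if r.converged and np.isfinite(r.t_stat):
                pseudo[k - bad] = r.t_stat
            else:
                bad += 1
        pseudo = pseudo[: n_perm - bad]
        n_eff = pseudo.size
        if n_eff < MIN_PERMUTATIONS:
            raise RuntimeError(
                f"only {n_eff} converged permutations; cannot form bounds"
            )
        lo, hi = np.percentile(pseudo, [2.5, 97.5])
        t_real = self.t_stat
        significant = bool(t_real < lo or t_real > hi)
        if t_real >= 0:
            count = int((pseudo > t_real).sum())
        else:
            count = int((pseudo < t_real).sum())
        return PermutationResult(
            t_real=float(t_real),
            pseudo_t=pseudo,
            bounds=(float(lo), float(hi)),
            p_value=pvalue_from_counts(count, n_eff),
            significant=significant,
            n_permutations=n_perm,
            n_effective=n_eff,
            n_nonconverged=bad,
            unreliable=bad > 0.1 * n_perm,
            family=self.model.family,
            seed=seed,
        )


def fit_glme(features: pd.DataFrame, family: str = "binomial",
             **kw) -> PainGlmeResults:
    """Fit the window model ``y ~ A + (A|temperature) + (A|patient)``."""
    return PainGlme(features, family=family).fit(**kw)


def permutation_test(features: pd.DataFrame, family: str = "binomial",
                     n_perm: int = 1000, rng_seed: int | None = None,
                     **kw) -> PermutationResult:
    """Fit and permutation-test one feature table (functional wrapper)."""
    fit = PainGlme(features, family=family).fit()
    return fit.permutation_test(n_perm=n_perm, seed=rng_seed, **kw)
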