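"""Per-library virome profiles, alpha/beta diversity, variance explained.

Alpha diversity is richness (viruses with nonzero count) and Shannon
entropy in nats; beta diversity is Bray–Curtis dissimilarity.  The
association between a virome metric (total abundance, richness,
diversity) and a library factor (sampling procedure, country, diet) is
measured with a one-way Gaussian linear model: R-squared plus a
likelihood-ratio chi-square p-value (ANOVA-of-GLM style), with a
classical F-test available as an option.  Fully aliased factor pairs
(e.g. when every whole-body library comes from one country) are refused
with a diagnostic rather than silently fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import braycurtis


@dataclass(frozen=True)
class ViromeProfile:
    """Alpha-diversity summary of one library's virome."""

    library_id: str
    richness: int
    shannon: float
    total_viral_percent: float
    per_clade: dict  # clade -> (n_genomes, summed percent_total)
    all_zero: bool = False


@dataclass(frozen=True)
class FactorAnalysisResult:
    response: str
    factor: str
    r_squared: float
    p_value: float
    test: str
    n_groups: int
    n_obs: int


def richness(counts) -> int:
    """Number of viruses with a nonzero count."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return int((arr > 0).sum())


def shannon(abundances) -> float:
    """Shannon entropy (nats) of a normalized abundance vector.

    An all-zero profile is reported as 0 (callers use the profile's
    ``all_zero`` flag to distinguish it from a true single-virus 0).
    """
    arr = np.asarray(abundances, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    total = arr.sum()
    if total == 0:
        return 0.0
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(profile_a, profile_b) -> float:
    """Bray-Curtis dissimilarity: sum|a-b| / sum(a+b), in [0, 1]."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must align")
    if a.sum() + b.sum() == 0:
        return 0.0
    return float(braycurtis(a, b))


def simpson(abundances) -> float:
    """Gini-Simpson diversity 1 - sum p_i^2 (alternative alpha index)."""
    arr = np.asarray(abundances, dtype=float)
    total = arr.sum()
    if total == 0:
        return 0.0
    p = arr / total
    return float(1.0 - (p**2).sum())


def factors_aliased(labels_a, labels_b) -> bool:
    """True when one factor's levels perfectly determine the other's
    (fully confounded, e.g. procedure vs country when all whole-body
    libraries come from one country)."""
    a = pd.Series(list(labels_a)).astype(str)
    b = pd.Series(list(labels_b)).astype(str)
    a_to_b = a.groupby(a).apply(lambda g: b[g.index].nunique() == 1).all()
    b_to_a = b.groupby(b).apply(lambda g: a[g.index].nunique() == 1).all()
    return bool(a_to_b and b_to_a)


def variance_explained(
    response,
    factor_labels,
    response_name: str = "response",
    factor_name: str = "factor",
    test: str = "chi-square-LRT",
) -> FactorAnalysisResult:
    """One-way Gaussian linear model of a virome metric on a library factor.

    R-squared is 1 - SS_residual/SS_total; the p-value comes from the
    likelihood-ratio chi-square against the intercept-only model
    (default) or from the classical F-test (``test='F'``).
    """
    y = np.asarray(response, dtype=float)
    labels = pd.Series([str(l) for l in factor_labels])
    if len(y) != len(labels):
        raise ValueError("response and factor labels must align")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    k = labels.nunique()
    if k < 2:
        raise ValueError(f"factor {factor_name!r} has one level")
    if test not in {"chi-square-LRT", "F"}:
        raise ValueError("test must be 'chi-square-LRT' or 'F'")

    design = pd.get_dummies(labels, drop_first=True, dtype=float)
    X = sm.add_constant(design.to_numpy())
    full = sm.OLS(y, X).fit()
    null = sm.OLS(y, np.ones((len(y), 1))).fit()
    if test == "F":
        p = float(full.f_pvalue)
    else:
        lr = 2.0 * (full.llf - null.llf)
        p = float(stats.chi2.sf(lr, df=k - 1))
    return FactorAnalysisResult(
        response=response_name,
        factor=factor_name,
        r_squared=float(full.rsquared),
        p_value=p,
        test=test,
        n_groups=int(k),
        n_obs=len(y),
    )


def virome_profiles(records, detections, library_ids) -> list[ViromeProfile]:
    """Per-library profiles over the curated (non-excluded) virus set."""
    dets_by_lib: dict[str, list] = {lib: [] for lib in library_ids}
    clade_of = {r.virus_name: r.clade for r in records}
    for d in detections:
        if d.library_id in dets_by_lib and d.virus_name in clade_of:
            dets_by_lib[d.library_id].append(d)
    profiles = []
    for lib in library_ids:
        dets = dets_by_lib[lib]
        per_clade: dict[str, tuple] = {}
        for d in dets:
            clade = clade_of[d.virus_name]
            n, s = per_clade.get(clade, (0, 0.0))
            per_clade[clade] = (n + 1, s + d.percent_total)
        abundances = [d.percent_total for d in dets]
        profiles.append(
            ViromeProfile(
                library_id=lib,
                richness=richness([d.read_count for d in dets]),
                shannon=shannon(abundances),
                total_viral_percent=float(sum(abundances)),
                per_clade=per_clade,
                all_zero=not dets,
            )
        )
    return profiles


def virome_matrix(records, detections, library_order) -> pd.DataFrame:
    """Clade × library table of (n_genomes, summed percent abundance).

    Cells are (count, percent) tuples; libraries follow the supplied
    (host-ordered) sequence.  A detection naming an unknown virus is an
    error.
    """
    clade_of = {r.virus_name: r.clade for r in records}
    unknown = {d.virus_name for d in detections} - set(clade_of)
    if unknown:
        raise ValueError(f"detections reference unknown viruses {sorted(unknown)}")
    clades = sorted({r.clade for r in records})
    data = {lib: {c: (0, 0.0) for c in clades} for lib in library_order}
    for d in detections:
        if d.library_id not in data:
            continue
        clade = clade_of[d.virus_name]
        n, s = data[d.library_id][clade]
        data[d.library_id][clade] = (n + 1, s + d.percent_total)
    return pd.DataFrame(data, index=clades, columns=list(library_order))


def distance_matrix(profiles_counts: pd.DataFrame) -> pd.DataFrame:
    """All-vs-all Bray-Curtis over a virus × library abundance table."""
    libs = list(profiles_counts.columns)
    m = np.zeros((len(libs), len(libs)))
    for i, a in enumerate(libs):
        for j in range(i + 1, len(libs)):
            d = bray_curtis(profiles_counts[a], profiles_counts[libs[j]])
            m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=libs, columns=libs)
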