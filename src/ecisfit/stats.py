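"""Replicate aggregation and reporting statistics.

The experimental unit is the independent experiment: each data point is
the mean over the electrodes of one well array (typically N = 4), and
independent experiments provide the replicates.  Whole-dataset variance is
tested by one-way fixed-effects ANOVA, reported in the compact form
``A(F;P)``; two-condition contrasts use Student's t-test (paired across
experiments for ECIS and colocalization, unpaired for qPCR).  qPCR
quantification uses the ΔΔCt method against a reference gene (default
HPRT) and a common reference sample.

The F and t statistics are computed from their classical closed forms
(pooled-variance Student form for the unpaired test; Welch available via
``equal_var=False``); P-values come from the corresponding scipy
distributions.  No multiple-testing correction is applied — a deliberate
match to common practice in this assay, documented as a limitation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InvalidArgumentError

__all__ = ["aggregate_electrodes", "anova_oneway", "ttest", "TTestResult",
           "ddct", "format_afp", "parse_afp"]

EXPERIMENT_COLUMNS = ["experiment_id", "condition", "electrode_id", "value"]
CT_COLUMNS = ["sample_id", "gene", "ct_cycles"]


def aggregate_electrodes(table: pd.DataFrame) -> pd.DataFrame:
    """Mean value per (experiment, condition) over its electrodes.

    ``table`` needs columns experiment_id, condition, electrode_id, value.
    Returns one row per group with the mean and the electrode count.
    """
    missing = [c for c in EXPERIMENT_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"experiment table missing columns: {missing}")
    if table.empty:
        raise DegenerateDataError("experiment table is empty")
    if table["value"].isna().any():
        raise InvalidArgumentError("experiment table contains missing values")
    out = (table.groupby(["experiment_id", "condition"], sort=True)["value"]
           .agg(mean="mean", n_electrodes="count").reset_index())
    return out


def anova_oneway(*groups) -> tuple:
    """Classical one-way fixed-effects ANOVA over ≥2 groups of replicate means.

    Returns ``(F, P)`` with F = MS_between / MS_within and P from the F
    distribution.  Degenerate cases: identical values everywhere give
    (0, 1); zero within-group variance with unequal means gives
    (inf, 0.0), which the formatter renders as a below-machine marker.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidArgumentError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise InvalidArgumentError("each ANOVA group needs at least two values")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n - k
    if df_within < 1:
        raise InvalidArgumentError("not enough residual degrees of freedom")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    mode: str
    degenerate: bool = False


def ttest(a, b, mode: str = "paired", equal_var: bool = True) -> TTestResult:
    """Two-tailed Student's t-test between two samples.

    paired
        t = mean(d) / (sd(d)/sqrt(n)) on the differences d = a - b,
        df = n - 1; requires equal lengths.
    unpaired
        pooled-variance Student form, df = n1 + n2 - 2, unless
        ``equal_var=False`` selects the Welch form.

    A zero-variance difference (or pooled) sample yields a degenerate
    result flagged explicitly rather than an exception or silent NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "paired":
        if len(a) != len(b):
            raise InvalidArgumentError("paired test requires equal-length samples")
        if len(a) < 2:
            raise InvalidArgumentError("paired test needs at least two pairs")
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        df = n - 1
        if sd == 0.0:
            return TTestResult(float("nan"), float("nan"), df, mode, degenerate=True)
        t = d.mean() / (sd / np.sqrt(n))
    elif mode == "unpaired":
        if len(a) < 2 or len(b) < 2:
            raise InvalidArgumentError("unpaired test needs at least two values per group")
        n1, n2 = len(a), len(b)
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            if sp2 == 0.0:
                return TTestResult(float("nan"), float("nan"), df, mode, degenerate=True)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        else:
            se2 = v1 / n1 + v2 / n2
            if se2 == 0.0:
                return TTestResult(float("nan"), float("nan"), n1 + n2 - 2, mode,
                                   degenerate=True)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            t = (a.mean() - b.mean()) / np.sqrt(se2)
    else:
        raise InvalidArgumentError("mode must be 'paired' or 'unpaired'")
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), p, df, mode)


def ddct(table: pd.DataFrame, reference_gene: str = "HPRT",
         reference_sample: str = "untreated") -> pd.DataFrame:
    """ΔCt / ΔΔCt relative quantification of a Ct table.

    ΔC(s, g)  = Ct(s, g) − Ct(s, reference_gene)
    ΔΔC(s, g) = ΔC(s, g) − ΔC(reference_sample, g)
    fold      = 2^−ΔΔC

    ``table`` needs columns sample_id, gene, ct_cycles; every sample must
    include the reference gene and the reference sample must cover every
    reported gene.  Adding a constant to all Ct values of one sample (a
    loading/efficiency offset) cancels exactly in ΔC.
    """
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidArgumentError(f"Ct table missing columns: {missing}")
    if not np.isfinite(table["ct_cycles"]).all():
        raise InvalidArgumentError("Ct values must be finite")
    wide = table.pivot_table(index="sample_id", columns="gene", values="ct_cycles",
                             aggfunc="mean")
    if reference_gene not in wide.columns:
        raise InvalidArgumentError(f"reference gene {reference_gene!r} absent from table")
    if wide[reference_gene].isna().any():
        bad = wide.index[wide[reference_gene].isna()].tolist()
        raise InvalidArgumentError(f"samples missing reference gene {reference_gene!r}: {bad}")
    if reference_sample not in wide.index:
        raise InvalidArgumentError(f"reference sample {reference_sample!r} absent from table")

    dc = wide.sub(wide[reference_gene], axis=0)
    genes = [g for g in wide.columns if g != reference_gene]
    if dc.loc[reference_sample, genes].isna().any():
        bad = [g for g in genes if np.isnan(dc.loc[reference_sample, g])]
        raise InvalidArgumentError(
            f"reference sample {reference_sample!r} missing genes: {bad}")
    ddc = dc.sub(dc.loc[reference_sample], axis=1)

    out = (ddc[genes].stack().rename("ddct").reset_index()
           .merge(dc[genes].stack().rename("dct").reset_index(),
                  on=["sample_id", "gene"]))
    out["fold_2_neg_ddct"] = 2.0 ** (-out["ddct"])
    return out[["sample_id", "gene", "dct", "ddct", "fold_2_neg_ddct"]]


def format_afp(f: float, p: float, precision: int = 3) -> str:
    """Render an ANOVA as the compact ``A(F;P)`` string.

    P below 1e-4 switches to scientific notation; an exactly-zero P (the
    zero-within-variance degenerate case) renders as a below-machine
    marker.
    """
    fs = f"{f:.{precision}g}"
    if p == 0.0:
        ps = "<1e-300"
    elif p < 1e-4:
        ps = f"{p:.{precision}e}"
    else:
        ps = f"{p:.{precision}g}"
    return f"A({fs};{ps})"


_AFP_RE = re.compile(r"^A\((?P<f>[^;]+);(?P<p><?[^)]+)\)$")


def parse_afp(s: str) -> tuple:
    """Inverse of :func:`format_afp` (at its rendered precision)."""
    m = _AFP_RE.match(s.strip())
    if m is None:
        raise InvalidArgumentError(f"not an A(F;P) string: {s!r}")
    f = float(m.group("f"))
    p_raw = m.group("p")
    p = 0.0 if p_raw.startswith("<") else float(p_raw)
    return f, p
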