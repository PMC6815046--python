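"""Case/control enrichment statistics for discovered gene modules.

Covers: classification of de novo variants into loss-of-function,
missense, synonymous, and other; a CADD deleteriousness filter for
missense variants; 2x2 case/control x in-/out-of-module contingency
tables with Fisher's exact test; label-permutation empirical p-values;
bootstrap confidence intervals for per-individual mutation rates;
gene-group rate comparisons; a phenotype annotation enrichment score;
and CNV-module overlap enrichment on half-open genomic intervals.

The Fisher p-value is computed from the exact (central) hypergeometric
distribution of the top-left cell conditional on the table margins; the
odds ratio is the unconditional cross-product ratio a*d / (b*c), with
+inf flagged when b*c = 0 while a*d > 0 and 1 when both products vanish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from seedmod.errors import InputError

logger = logging.getLogger(__name__)

GENOME_TOTAL_DEFAULT = 19_986

#: Functional-class vocabulary, normalised to lowercase hyphenated form.
LOF_CLASSES = frozenset(
    {
        "frameshift",
        "splice-donor",
        "splice-acceptor",
        "stop-gained",
        "stop-gained-near-splice",
        "stop-lost",
    }
)
MISSENSE_CLASSES = frozenset({"missense", "missense-near-splice"})
SYNONYMOUS_CLASSES = frozenset({"synonymous", "coding-synonymous", "synonymous-near-splice"})
NON_SYNONYMOUS = ("LOF", "missense")

VARIANT_COLUMNS = ["sample_id", "group", "cohort", "gene", "functional_class", "cadd"]


def _normalise_class(label: str) -> str:
    return str(label).strip().lower().replace("_", "-").replace(" ", "-")


def classify_functional(label: str) -> str:
    """Map a functional-class string to LOF / missense / synonymous / other."""
    norm = _normalise_class(label)
    if norm in LOF_CLASSES:
        return "LOF"
    if norm in MISSENSE_CLASSES:
        return "missense"
    if norm in SYNONYMOUS_CLASSES:
        return "synonymous"
    return "other"


def read_variant_table(path) -> pd.DataFrame:
    """Read a TSV of de novo variant records.

    Columns: sample_id, group (case/control), cohort, gene,
    functional_class, optional cadd.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "gene": str})
    missing = [c for c in VARIANT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise InputError(f"variant table {path} missing columns: {missing}")
    if "cadd" not in df.columns:
        df["cadd"] = np.nan
    if (df["sample_id"].astype(str).str.len() == 0).any():
        raise InputError("variant table has empty sample_id values")
    return df


def classify_variants(vt: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the variant table with a ``mut_class`` column added.

    Unknown functional classes map to "other" with a logged warning.
    Record counts are conserved: every input row appears exactly once.
    """
    out = vt.copy()
    out["mut_class"] = out["functional_class"].map(classify_functional)
    unknown = sorted(
        set(
            _normalise_class(c)
            for c in out.loc[out["mut_class"] == "other", "functional_class"]
        )
        - LOF_CLASSES
        - MISSENSE_CLASSES
        - SYNONYMOUS_CLASSES
    )
    known_other = {"intron", "intergenic", "utr", "3-prime-utr", "5-prime-utr", "upstream", "downstream"}
    odd = [c for c in unknown if c not in known_other]
    if odd:
        logger.warning("unknown functional classes mapped to 'other': %s", ", ".join(odd))
    return out


def tabulate_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-cohort, per-class mutation counts (long format)."""
    return (
        classified.groupby(["gene", "cohort", "mut_class"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )


def cadd_filter(vt: pd.DataFrame, threshold: float = 15.0) -> pd.DataFrame:
    """Keep only penetrant missense variants (CADD > threshold).

    Missense records with CADD <= threshold, or with no CADD score, are
    removed; all other classes pass through untouched.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    classes = vt["functional_class"].map(classify_functional)
    is_missense = classes == "missense"
    keep = ~is_missense | (vt["cadd"].astype(float) > threshold)
    return vt.loc[keep.fillna(False)].copy()


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows case/control, columns in-module / out-of-module counts."""

    a: int  # case, in module
    b: int  # case, outside
    c: int  # control, in module
    d: int  # control, outside

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    """Odds ratio and p-values for one enrichment test."""

    odds_ratio: float  # may be inf
    fisher_p: float
    perm_p: float | None = None
    ci: tuple[float, float] | None = None
    n_iter: int | None = None
    rng_seed: int | None = None
    table: ContingencyTable | None = None


def build_contingency(
    module_genes,
    classified: pd.DataFrame,
    case_cohorts=None,
    mut_classes=NON_SYNONYMOUS,
    universe_genes=None,
) -> ContingencyTable:
    """Tally case/control mutations inside vs outside a module.

    "Outside" is taken relative to the gene universe when one is given.
    ``case_cohorts`` restricts the case arm to specific cohort labels;
    control records (group == "control") are always the comparison arm.
    """
    module_genes = set(module_genes)
    if not module_genes:
        raise InputError("module gene set is empty")
    df = classified
    if mut_classes is not None:
        df = df[df["mut_class"].isin(set(mut_classes))]
    if universe_genes is not None:
        df = df[df["gene"].isin(set(universe_genes))]
    is_control = df["group"] == "control"
    is_case = df["group"] == "case"
    if case_cohorts is not None:
        is_case &= df["cohort"].isin(set(case_cohorts))
    in_mod = df["gene"].isin(module_genes)
    return ContingencyTable(
        a=int((is_case & in_mod).sum()),
        b=int((is_case & ~in_mod).sum()),
        c=int((is_control & in_mod).sum()),
        d=int((is_control & ~in_mod).sum()),
    )


def odds_ratio(ct: ContingencyTable) -> float:
    """Cross-product ratio with +inf / indeterminate-as-1 flags for zero cells."""
    ad, bc = ct.a * ct.d, ct.b * ct.c
    if bc == 0:
        return float("inf") if ad > 0 else 1.0
    return ad / bc


def fisher_p_greater(a, m, n, k):
    """P(X >= a) for X ~ Hypergeom drawing m of m+n items with k marked.

    Vectorised over numpy arrays; this is the one-sided (enrichment)
    Fisher exact p-value for tables with row margins m, n and first
    column margin k.
    """
    a = np.asarray(a)
    return stats.hypergeom.sf(a - 1, np.asarray(m) + np.asarray(n), k, m)


def _fisher_p_two_sided(ct: ContingencyTable) -> float:
    m, n, k = ct.a + ct.b, ct.c + ct.d, ct.a + ct.c
    lo, hi = max(0, k - n), min(k, m)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, m + n, k, m)
    p_obs = stats.hypergeom.pmf(ct.a, m + n, k, m)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_test(ct: ContingencyTable, alternative: str = "greater") -> EnrichmentResult:
    """Fisher's exact test on a 2x2 case/control x in/out table."""
    if ct.total == 0:
        raise InputError("all-zero contingency table")
    if alternative == "greater":
        p = float(fisher_p_greater(ct.a, ct.a + ct.b, ct.c + ct.d, ct.a + ct.c))
    elif alternative == "two-sided":
        p = _fisher_p_two_sided(ct)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return EnrichmentResult(odds_ratio=odds_ratio(ct), fisher_p=min(1.0, max(p, 0.0)), table=ct)


def _per_sample_counts(classified, module_genes, mut_classes, case_cohorts):
    """Per-sample (in-module, out-module) mutation counts plus group labels.

    The sample roster covers every individual present in the table for
    the selected cohorts, including those with no mutation in the
    selected classes (their counts are 0); leaving them out would bias
    the permutation null.
    """
    df = classified
    if case_cohorts is not None:
        keep = (df["group"] == "control") | df["cohort"].isin(set(case_cohorts))
        df = df[keep]
    roster = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    if mut_classes is not None:
        df = df[df["mut_class"].isin(set(mut_classes))]
    in_mod = df["gene"].isin(set(module_genes))
    per = pd.DataFrame(
        {
            "in_mod": df[in_mod].groupby("sample_id").size().reindex(roster.index),
            "out_mod": df[~in_mod].groupby("sample_id").size().reindex(roster.index),
        }
    ).fillna(0)
    per["group"] = roster
    return per


def _or_vec(a, b, c, d):
    ad = a * d
    bc = b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bc == 0, np.where(ad > 0, np.inf, 1.0), ad / np.maximum(bc, 1e-300))
    return out


def permutation_test(
    classified: pd.DataFrame,
    module_genes,
    n_iter: int = 5000,
    rng_seed: int = 0,
    mut_classes=NON_SYNONYMOUS,
    case_cohorts=None,
) -> EnrichmentResult:
    """Empirical enrichment p-value by permuting case/control sample labels.

    Per-sample mutation lists are preserved; only arm assignments are
    shuffled.  p = (1 + #{permuted OR >= observed OR}) / (n_iter + 1),
    deterministic for a fixed ``rng_seed``.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    per = _per_sample_counts(classified, module_genes, mut_classes, case_cohorts)
    if len(per) < 2:
        raise InputError("permutation test needs at least 2 distinct samples")
    in_mod = per["in_mod"].to_numpy(float)
    out_mod = per["out_mod"].to_numpy(float)
    is_case = (per["group"] == "case").to_numpy()
    n_case = int(is_case.sum())
    tot_in, tot_out = in_mod.sum(), out_mod.sum()

    obs = _or_vec(
        in_mod[is_case].sum(), out_mod[is_case].sum(),
        tot_in - in_mod[is_case].sum(), tot_out - out_mod[is_case].sum(),
    )
    rng = np.random.default_rng(rng_seed)
    a = np.empty(n_iter)
    b = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.permutation(len(per))[:n_case]
        a[i] = in_mod[idx].sum()
        b[i] = out_mod[idx].sum()
    ors = _or_vec(a, b, tot_in - a, tot_out - b)
    hits = int(np.sum(ors >= obs))
    p = (1 + hits) / (n_iter + 1)
    return EnrichmentResult(
        odds_ratio=float(obs), fisher_p=float("nan"), perm_p=p, n_iter=n_iter, rng_seed=rng_seed
    )


def bootstrap_rates(
    classified: pd.DataFrame,
    gene_group,
    n_iter: int = 20_000,
    rng_seed: int = 0,
    mut_classes=NON_SYNONYMOUS,
    samples: dict[str, list] | None = None,
) -> dict[str, dict]:
    """Bootstrap the mean per-individual mutation count in a gene group.

    Individuals are resampled with replacement within each arm; the
    2.5/97.5 percentile interval is reported.  ``samples`` may supply
    the full roster per arm (including individuals with zero recorded
    mutations); by default the distinct sample ids present in the table
    define each arm.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    gene_group = set(gene_group)
    df = classified
    if mut_classes is not None:
        df = df[df["mut_class"].isin(set(mut_classes))]
    hits = df[df["gene"].isin(gene_group)]
    per_sample = hits.groupby("sample_id").size()
    rng = np.random.default_rng(rng_seed)
    out: dict[str, dict] = {}
    for arm in ("case", "control"):
        if samples is not None:
            roster = list(samples[arm])
        else:
            roster = sorted(classified.loc[classified["group"] == arm, "sample_id"].unique())
        if not roster:
            raise InputError(f"no individuals in arm {arm!r}")
        counts = per_sample.reindex(roster).fillna(0).to_numpy(float)
        n = len(counts)
        means = np.empty(n_iter)
        chunk = max(1, min(n_iter, int(4e6 // max(n, 1))))
        for start in range(0, n_iter, chunk):
            stop = min(start + chunk, n_iter)
            idx = rng.integers(0, n, size=(stop - start, n))
            means[start:stop] = counts[idx].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        out[arm] = {
            "mean": float(counts.mean()),
            "ci": (float(lo), float(hi)),
            "n": n,
            "n_iter": n_iter,
        }
    return out


def gene_group_rate_comparison(
    classified: pd.DataFrame,
    groups: dict[str, set],
    n_cases: int | None = None,
    n_controls: int | None = None,
    mut_classes=("LOF", "missense", "synonymous", "non-synonymous"),
) -> pd.DataFrame:
    """Compare per-individual mutation rates per gene group and class.

    The p-value is a two-sided exact binomial allocation test: given
    the total count in a group/class, case mutations are binomial with
    success probability n_cases / (n_cases + n_controls) under equal
    per-individual rates.
    """
    if n_cases is None:
        n_cases = classified.loc[classified["group"] == "case", "sample_id"].nunique()
    if n_controls is None:
        n_controls = classified.loc[classified["group"] == "control", "sample_id"].nunique()
    if n_cases < 1 or n_controls < 1:
        raise InputError("both arms must contain at least one individual")
    p_null = n_cases / (n_cases + n_controls)
    rows = []
    for name, genes in groups.items():
        genes = set(genes)
        if not genes:
            logger.warning("gene group %r is empty; skipped", name)
            continue
        sub = classified[classified["gene"].isin(genes)]
        for mc in mut_classes:
            if mc == "non-synonymous":
                part = sub[sub["mut_class"].isin(NON_SYNONYMOUS)]
            else:
                part = sub[sub["mut_class"] == mc]
            cc = int((part["group"] == "case").sum())
            kc = int((part["group"] == "control").sum())
            case_rate = cc / n_cases
            ctrl_rate = kc / n_controls
            if kc == 0:
                ratio = float("inf") if cc > 0 else float("nan")
            else:
                ratio = case_rate / ctrl_rate
            total = cc + kc
            p = 1.0 if total == 0 else stats.binomtest(cc, total, p_null).pvalue
            rows.append(
                {
                    "group": name,
                    "mut_class": mc,
                    "case_count": cc,
                    "control_count": kc,
                    "case_rate": case_rate,
                    "control_rate": ctrl_rate,
                    "rate_ratio": ratio,
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PhenotypeAnnotation:
    """Phenotype label -> annotated gene set, with the genome-wide total."""

    gene_sets: dict[str, set]
    genome_total: int = GENOME_TOTAL_DEFAULT

    def __post_init__(self) -> None:
        for label, genes in self.gene_sets.items():
            if not genes:
                raise InputError(f"phenotype {label!r} has an empty gene set")
            if len(genes) > self.genome_total:
                raise InputError(f"phenotype {label!r} annotates more genes than genome_total")

    @classmethod
    def from_tsv(cls, path, genome_total: int = GENOME_TOTAL_DEFAULT) -> "PhenotypeAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise InputError(f"annotation {path} needs columns phenotype, gene")
        sets: dict[str, set] = {}
        for pheno, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
            sets.setdefault(str(pheno), set()).add(str(gene))
        return cls(sets, genome_total)


def phenotype_enrichment_score(
    module_genes,
    annotation: PhenotypeAnnotation,
    phenotype: str,
) -> float:
    """Module annotation odds over genome-wide annotation odds.

    score = (M_P / M_P') / (G_P / (genome_total - G_P)) where M_P is the
    number of annotated module genes, M_P' = |module| - M_P, and G_P the
    genome-wide annotated count.  Score 0 when no module gene is
    annotated; +inf when the whole module is annotated.
    """
    module_genes = set(module_genes)
    if not module_genes:
        raise InputError("module gene set is empty")
    pheno_genes = annotation.gene_sets[phenotype]
    g_p = len(pheno_genes)
    if g_p >= annotation.genome_total:
        raise InputError("phenotype annotates the entire genome; odds undefined")
    m_p = len(module_genes & pheno_genes)
    m_pc = len(module_genes) - m_p
    if m_p == 0:
        return 0.0
    if m_pc == 0:
        return float("inf")
    return (m_p / m_pc) / (g_p / (annotation.genome_total - g_p))


def read_cnv_table(path) -> pd.DataFrame:
    """BED-like TSV of CNVs: chrom, start, end, sample_id, group, type."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample_id": str})
    needed = {"chrom", "start", "end", "sample_id", "group", "type"}
    missing = needed - set(df.columns)
    if missing:
        raise InputError(f"CNV table {path} missing columns: {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        raise InputError("CNV intervals must satisfy start < end (0-based half-open)")
    return df


def read_gene_intervals(path) -> pd.DataFrame:
    """BED-like TSV of gene intervals: chrom, start, end, gene."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "gene": str})
    needed = {"chrom", "start", "end", "gene"}
    missing = needed - set(df.columns)
    if missing:
        raise InputError(f"gene intervals {path} missing columns: {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        raise InputError("gene intervals must satisfy start < end (0-based half-open)")
    return df


def cnv_hits_module(cnvs: pd.DataFrame, intervals: pd.DataFrame, module_genes) -> np.ndarray:
    """Boolean per-CNV flag: does it intersect any module gene by >= 1 bp?

    All coordinates are 0-based half-open; intervals [s1, e1) and
    [s2, e2) intersect iff s1 < e2 and s2 < e1.
    """
    module_iv = intervals[intervals["gene"].isin(set(module_genes))]
    hits = np.zeros(len(cnvs), dtype=bool)
    for chrom, sub in module_iv.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        mask = (cnvs["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        c_start = cnvs.loc[mask, "start"].to_numpy()[:, None]
        c_end = cnvs.loc[mask, "end"].to_numpy()[:, None]
        hits[mask] |= ((c_start < ends[None, :]) & (starts[None, :] < c_end)).any(axis=1)
    return hits


def cnv_overlap_enrichment(
    cnvs: pd.DataFrame,
    intervals: pd.DataFrame,
    module_genes,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> EnrichmentResult:
    """Case/control enrichment of CNVs intersecting module genes.

    Contingency: case/control x (CNV hits >= 1 module gene / does not);
    Fisher odds ratio plus a sample-label-permutation empirical p-value.
    """
    if len(cnvs) == 0:
        raise InputError("CNV table is empty")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    hits = cnv_hits_module(cnvs, intervals, module_genes)
    per = pd.DataFrame({"sample_id": cnvs["sample_id"], "hit": hits, "group": cnvs["group"]})
    by_sample = per.groupby("sample_id").agg(
        hit=("hit", "sum"), total=("hit", "size"), group=("group", "first")
    )
    h = by_sample["hit"].to_numpy(float)
    t = by_sample["total"].to_numpy(float)
    is_case = (by_sample["group"] == "case").to_numpy()
    n_case = int(is_case.sum())
    a, b = h[is_case].sum(), (t - h)[is_case].sum()
    c, d = h.sum() - a, (t - h).sum() - b
    ct = ContingencyTable(int(a), int(b), int(c), int(d))
    obs = odds_ratio(ct)
    fisher = fisher_test(ct, alternative="greater")
    rng = np.random.default_rng(rng_seed)
    pa = np.empty(n_perm)
    pb = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(len(by_sample))[:n_case]
        pa[i] = h[idx].sum()
        pb[i] = (t - h)[idx].sum()
    ors = _or_vec(pa, pb, h.sum() - pa, (t - h).sum() - pb)
    p = (1 + int(np.sum(ors >= obs))) / (n_perm + 1)
    return EnrichmentResult(
        odds_ratio=obs,
        fisher_p=fisher.fisher_p,
        perm_p=p,
        n_iter=n_perm,
        rng_seed=rng_seed,
        table=ct,
    )
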