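"""Mendelian segregation statistics and genotype-phenotype co-segregation.

Two-class goodness-of-fit chi-square with one degree of freedom, testing
observed phenotype counts against an expected ratio (3:1 for an F2 of a
monogenic recessive, 1:1 for a backcross to the mutant). The Yates
continuity correction is on by default with a floor at zero:

    chi2 = sum_i max(|O_i - E_i| - 0.5, 0)^2 / E_i

which is the form consistent with the statistics this package is expected
to reproduce for segregating F2/BC1 populations.

Co-segregation checks a KASP-style genotype table against phenotypes for a
recessive mutation: every mutant-phenotype plant must be homozygous for the
mutant allele, and every wild-type-phenotype plant must carry at least one
wild-type allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2 as chi2_dist


@dataclass
class SegregationTest:
    observed: tuple[int, int]
    expected_ratio: tuple[float, float]
    chi2: float  # exact value; round to 3 decimals for tabular reporting
    df: int
    p_value: float
    yates: bool

    def to_dict(self) -> dict:
        a, b = self.observed
        return {
            "observed": list(self.observed),
            "expected_ratio": list(self.expected_ratio),
            "segregation_ratio": segregation_ratio(self.observed) if b > 0 else None,
            "chi2": round(self.chi2, 3),
            "df": self.df,
            "p_value": self.p_value,
            "yates": self.yates,
        }


def segregation_ratio(observed: tuple[int, int]) -> float:
    """Class-A : class-B ratio reported to 3 decimals (e.g. 321:89 -> 3.607)."""
    a, b = observed
    if b <= 0:
        raise ValueError("class B count must be positive to form a ratio")
    return round(a / b, 3)


def chi_square_gof(
    observed: tuple[int, int],
    ratio: tuple[float, float] = (3, 1),
    yates: bool = True,
) -> SegregationTest:
    """One-df goodness of fit of two observed class counts to a ratio."""
    a, b = observed
    if a < 0 or b < 0:
        raise ValueError("observed counts must be non-negative")
    total = a + b
    if total == 0:
        raise ValueError("total count must be positive")
    ra, rb = ratio
    if ra <= 0 or rb <= 0:
        raise ValueError("ratio shares must be positive")
    expected = (total * ra / (ra + rb), total * rb / (ra + rb))
    if yates:
        stat = sum(
            max(abs(o - e) - 0.5, 0.0) ** 2 / e for o, e in zip(observed, expected)
        )
    else:
        stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return SegregationTest(
        observed=(a, b),
        expected_ratio=(float(ra), float(rb)),
        chi2=stat,
        df=1,
        p_value=float(chi2_dist.sf(stat, df=1)),
        yates=yates,
    )


@dataclass
class CosegregationResult:
    n_plants: int
    n_mutant_phenotype: int
    n_concordant: int
    consistent: bool
    discordant_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "n_plants": self.n_plants,
            "n_mutant_phenotype": self.n_mutant_phenotype,
            "n_concordant": self.n_concordant,
            "consistent": self.consistent,
            "discordant_ids": list(self.discordant_ids),
        }


def check_recessive_cosegregation(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    mutant_allele: str,
) -> CosegregationResult:
    """Check that a candidate SNP co-segregates with a recessive phenotype.

    ``genotypes`` needs columns plant_id, genotype (``X:Y``); ``phenotypes``
    needs plant_id, phenotype in {wild_type, mutant}. A plant present in only
    one table is an error.
    """
    g = genotypes.set_index("plant_id")["genotype"]
    p = phenotypes.set_index("plant_id")["phenotype"]
    if g.index.has_duplicates or p.index.has_duplicates:
        raise ValueError("duplicate plant_id in input table")
    only = set(g.index) ^ set(p.index)
    if only:
        raise ValueError(f"plants present in one table only: {sorted(only)[:5]}")
    discordant: list[str] = []
    n_mut = 0
    for plant_id in g.index:
        alleles = g[plant_id].split(":")
        hom_mutant = all(a == mutant_allele for a in alleles)
        if p[plant_id] == "mutant":
            n_mut += 1
            concordant = hom_mutant
        else:
            concordant = not hom_mutant
        if not concordant:
            discordant.append(str(plant_id))
    n = len(g)
    return CosegregationResult(
        n_plants=n,
        n_mutant_phenotype=n_mut,
        n_concordant=n - len(discordant),
        consistent=not discordant,
        discordant_ids=discordant,
    )
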