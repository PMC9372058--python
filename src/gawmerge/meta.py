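"""Fixed-effect inverse-variance meta-analysis with direction strings.

Per-study log odds ratios are combined with weights 1/SE^2; the
direction string carries one character per study in fixed input order:
"+" or "-" for the sign of that study's effect, "?" when the study
lacks the variant (absent by design or removed by its filters).
A sample-size-weighted Z combination is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigError, FormatError

__all__ = ["MetaRecord", "inverse_variance_meta", "combine_analyses"]

META_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "BETA", "SE", "P", "OR",
    "DIRECTION", "N_STUDIES",
]


@dataclass(frozen=True)
class MetaRecord:
    beta: float
    se: float
    p: float
    direction: str
    n_studies: int


def inverse_variance_meta(per_study: list[tuple[float, float] | None]) -> MetaRecord:
    """Combine per-study (beta, se) pairs; ``None`` marks an absent study."""
    present = [(b, s) for bs in per_study if bs is not None for b, s in [bs]]
    if not present:
        raise ConfigError("no studies present for variant")
    for _, s in present:
        if not (s > 0):
            raise ConfigError("present study must have positive SE")
    w = np.array([1.0 / s**2 for _, s in present])
    b = np.array([b for b, _ in present])
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = "".join(
        "?" if bs is None else ("+" if bs[0] >= 0 else "-") for bs in per_study
    )
    return MetaRecord(beta, se, max(p, 5e-324), direction, len(present))


def sample_size_meta(
    per_study: list[tuple[float, float, int] | None]
) -> tuple[float, float]:
    """Sample-size-weighted Z combination: (z, p) from (beta, se, n) pairs."""
    present = [t for t in per_study if t is not None]
    if not present:
        raise ConfigError("no studies present for variant")
    z = np.array([b / s for b, s, _ in present])
    w = np.sqrt(np.array([n for _, _, n in present], dtype=float))
    zc = float((w * z).sum() / np.sqrt((w**2).sum()))
    return zc, float(2.0 * stats.norm.sf(abs(zc)))


def combine_analyses(
    tables: list[pd.DataFrame], study_labels: list[str] | None = None
) -> pd.DataFrame:
    """Meta-analyse PASS records of several association tables.

    The union of PASS variants across studies is combined per variant;
    a study where the variant is absent or filtered contributes "?".
    Allele orientation must agree across studies (error otherwise).
    """
    if study_labels is None:
        study_labels = [f"study{i + 1}" for i in range(len(tables))]
    if len(study_labels) != len(tables):
        raise ConfigError("study_labels length mismatch")

    per_study_maps = []
    alleles: dict = {}
    for t in tables:
        m = {}
        sub = t[t["FILTER"] == "PASS"]
        for _, row in sub.iterrows():
            key = (row["CHROM"], int(row["POS"]))
            al = (row["REF"], row["ALT"])
            if key in alleles and alleles[key] != al:
                raise FormatError(f"inconsistent alleles for {key}")
            alleles[key] = al
            m[key] = (float(row["BETA"]), float(row["SE"]))
        per_study_maps.append(m)

    union = sorted(set().union(*[set(m) for m in per_study_maps]))
    rows = []
    for key in union:
        per = [m.get(key) for m in per_study_maps]
        rec = inverse_variance_meta(per)
        ref, alt = alleles[key]
        rows.append(
            {
                "CHROM": key[0],
                "POS": key[1],
                "REF": ref,
                "ALT": alt,
                "BETA": rec.beta,
                "SE": rec.se,
                "P": rec.p,
                "OR": float(np.exp(rec.beta)),
                "DIRECTION": rec.direction,
                "N_STUDIES": rec.n_studies,
            }
        )
    return pd.DataFrame(rows, columns=META_COLUMNS)
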