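"""CSV readers and writers for the pipeline's tabular interchange formats."""

from __future__ import annotations

import math

import pandas as pd

from .ddpcr import CopyNumberCall, DropletWell
from .errors import CnvDropError
from .genotype import CnvGenotype
from .qpcr import CtReplicateSet

WELLS_COLUMNS = ["sample_id", "assay_id", "n_accepted", "n_pos_target", "n_pos_ref"]
CALLS_COLUMNS = [
    "sample_id", "locus", "method", "cn_estimate", "ci_low", "ci_high", "qc_flags",
]
GENOTYPES_COLUMNS = [
    "sample_id", "locus", "total_cn", "alleles", "confidence", "flags",
]


def read_wells_csv(path) -> list[DropletWell]:
    """Read one-row-per-well droplet counts."""
    df = pd.read_csv(path)
    missing = set(WELLS_COLUMNS) - set(df.columns)
    if missing:
        raise CnvDropError(f"wells CSV missing columns: {sorted(missing)}")
    return [
        DropletWell(
            sample_id=str(r.sample_id),
            assay_id=str(r.assay_id),
            n_accepted=int(r.n_accepted),
            n_pos_target=int(r.n_pos_target),
            n_pos_ref=int(r.n_pos_ref),
        )
        for r in df.itertuples()
    ]


def write_wells_csv(wells: list[DropletWell], path) -> None:
    pd.DataFrame(
        [
            (w.sample_id, w.assay_id, w.n_accepted, w.n_pos_target, w.n_pos_ref)
            for w in wells
        ],
        columns=WELLS_COLUMNS,
    ).to_csv(path, index=False)


def write_calls_csv(calls: list[CopyNumberCall], path) -> None:
    pd.DataFrame(
        [
            (
                c.sample_id, c.locus, c.method,
                c.cn_estimate, c.ci_low, c.ci_high,
                ";".join(sorted(c.qc_flags)),
            )
            for c in calls
        ],
        columns=CALLS_COLUMNS,
    ).to_csv(path, index=False)


def read_calls_csv(path) -> list[CopyNumberCall]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        CopyNumberCall(
            sample_id=str(r.sample_id),
            locus=str(r.locus),
            method=str(r.method),
            cn_estimate=float(r.cn_estimate),
            ci_low=float(r.ci_low),
            ci_high=float(r.ci_high),
            qc_flags=frozenset(
                f for f in str(r.qc_flags).split(";") if f
            ),
        )
        for r in df.itertuples()
    ]


def read_ct_csv(path) -> list[CtReplicateSet]:
    """Read Ct replicate rows: sample_id, assay_id, dye, ct1..ct4.

    Blank cells mark missing replicates and are dropped.
    """
    df = pd.read_csv(path)
    ct_cols = [c for c in df.columns if c.startswith("ct")]
    sets = []
    for r in df.itertuples():
        values = tuple(
            float(getattr(r, c))
            for c in ct_cols
            if not _is_blank(getattr(r, c))
        )
        sets.append(
            CtReplicateSet(str(r.sample_id), str(r.assay_id), str(r.dye), values)
        )
    return sets


def _is_blank(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x == ""


def write_genotypes_csv(genotypes: list[CnvGenotype | None], path) -> None:
    rows = []
    for g in genotypes:
        if g is None:
            continue
        rows.append(
            (
                g.sample_id, g.locus, g.total_cn, g.allele_string,
                round(g.confidence, 6), ";".join(sorted(g.flags)),
            )
        )
    pd.DataFrame(rows, columns=GENOTYPES_COLUMNS).to_csv(path, index=False)


def read_genotypes_csv(path) -> list[CnvGenotype]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        CnvGenotype.from_string(
            str(r.sample_id),
            str(r.locus),
            str(r.alleles),
            confidence=float(r.confidence),
            flags=frozenset(f for f in str(r.flags).split(";") if f),
        )
        for r in df.itertuples()
    ]


def read_phenotypes_csv(path) -> pd.DataFrame:
    """Phenotype table: sample_id plus 1/0/NA phenotype columns."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise CnvDropError("phenotype CSV needs a sample_id column")
    return df
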