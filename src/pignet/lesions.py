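"""Skin-lesion outcome variables per pig, body region and timepoint.

Fresh lesions are counted on the anterior, central and posterior body
regions immediately before mixing, 24 h later, and at one and two weeks.
The acute outcome is the 24 h increase over the pre-mixing baseline,
floored at zero.  At one and two weeks, counts are used as-is (fresh
lesions only); the sparse central and posterior regions are reduced to
presence/absence while the anterior region stays a count.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TIMEPOINTS = ("pre", "24h", "1wk", "2wk")
REGIONS = ("anterior", "central", "posterior")
SPARSE_REGIONS = ("central", "posterior")
LESION_COLUMNS = ["pig", "timepoint", "region", "count"]


@dataclass(frozen=True)
class LesionCount:
    pig: str
    timepoint: str
    region: str
    count: int

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.count < 0:
            raise ValueError("lesion count must be >= 0")


def lesion_delta(pre: LesionCount, post24: LesionCount) -> int:
    """24 h lesion gain: post-mixing count minus baseline, floored at zero."""
    if pre.pig != post24.pig:
        raise ValueError(f"pig mismatch: {pre.pig!r} vs {post24.pig!r}")
    if pre.region != post24.region:
        raise ValueError(f"region mismatch: {pre.region!r} vs {post24.region!r}")
    if pre.timepoint != "pre" or post24.timepoint != "24h":
        raise ValueError("lesion_delta expects a 'pre' and a '24h' record")
    return max(0, post24.count - pre.count)


def binarize_sparse(record: LesionCount) -> bool:
    """Presence/absence of fresh lesions in a sparse region at 1wk/2wk."""
    if record.timepoint not in ("1wk", "2wk"):
        raise ValueError("binarisation applies to 1wk/2wk counts only")
    if record.region not in SPARSE_REGIONS:
        raise ValueError(
            f"{record.region!r} stays a count; binarisation applies to "
            f"{SPARSE_REGIONS}"
        )
    return record.count > 0


def load_lesions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"pig": str})
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing lesion columns: {missing}")
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    bad_rg = set(df["region"]) - set(REGIONS)
    if bad_rg:
        raise ValueError(f"unknown regions: {sorted(bad_rg)}")
    if (df["count"] < 0).any():
        raise ValueError("negative lesion counts")
    return df


def lesion_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    """Per-pig derived lesion outcomes.

    Columns: ``delta24_<region>`` (floored 24 h gain per region),
    ``anterior_1wk`` / ``anterior_2wk`` (counts), and
    ``<region>_<tp>_any`` presence flags for the sparse regions.
    """
    wide = df.pivot_table(
        index="pig", columns=["timepoint", "region"], values="count", aggfunc="first"
    )
    out = pd.DataFrame(index=wide.index)
    for region in REGIONS:
        pre = wide.get(("pre", region))
        post = wide.get(("24h", region))
        if pre is not None and post is not None:
            out[f"delta24_{region}"] = (post - pre).clip(lower=0)
    for tp in ("1wk", "2wk"):
        col = wide.get((tp, "anterior"))
        if col is not None:
            out[f"anterior_{tp}"] = col
        for region in SPARSE_REGIONS:
            col = wide.get((tp, region))
            if col is not None:
                out[f"{region}_{tp}_any"] = (col > 0).astype(int)
    return out.reset_index()
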