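"""Reading, writing and validation of the long-format quant-table dialect,
plus the peptide-form identifier parser.

The dialect is a normalized long CSV, one row per (feature, run):

    feature_id,feature_type,protein_id,family_id,form_id,condition,stage,point,replicate,intensity

``feature_type`` is one of ``protein``, ``peptide`` or ``trypsin_ref``;
``point`` one of ``start``, ``end``, ``extension``. Peptide-form identifiers
encode residue coordinates in the form ``SEQ[start-end]`` (1-based inclusive,
matching the subscript convention of proteomics figures), optionally with
single flanking residues, e.g. ``K-CNVNVPYTISPDIDCSR[99-115]-I``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "QuantTableError",
    "FormCoordinates",
    "read_quant_table",
    "write_quant_table",
    "validate_quant_table",
    "parse_form_id",
]

log = logging.getLogger("micromash")

REQUIRED_COLUMNS = [
    "feature_id",
    "feature_type",
    "protein_id",
    "family_id",
    "form_id",
    "condition",
    "stage",
    "point",
    "replicate",
    "intensity",
]
FEATURE_TYPES = {"protein", "peptide", "trypsin_ref"}
POINTS = {"start", "end", "extension"}
KEY = ["feature_id", "condition", "stage", "point", "replicate"]


class QuantTableError(ValueError):
    """Raised on a malformed quant table or identifier."""


@dataclass(frozen=True)
class FormCoordinates:
    """Residue coordinates of a peptide form, optionally against its parent.

    Coordinates are 1-based inclusive. When a parent range is supplied the
    terminal flags are derived: a form is full-tryptic exactly when its range
    equals the parent range; a later start makes it N-ragged, an earlier end
    C-ragged (one physiological terminus each).
    """

    sequence: str
    start: int
    end: int
    prefix: str = ""
    suffix: str = ""
    parent_start: int | None = None
    parent_end: int | None = None

    @property
    def n_ragged(self) -> bool:
        self._need_parent()
        return self.start > self.parent_start

    @property
    def c_ragged(self) -> bool:
        self._need_parent()
        return self.end < self.parent_end

    @property
    def full_tryptic(self) -> bool:
        self._need_parent()
        return self.start == self.parent_start and self.end == self.parent_end

    def _need_parent(self):
        if self.parent_start is None or self.parent_end is None:
            raise QuantTableError("terminal flags need a parent range")


_FORM_RE = re.compile(
    r"^(?:(?P<prefix>[A-Z])-)?(?P<seq>[A-Z]+)\[(?P<start>\d+)-(?P<end>\d+)\]"
    r"(?:-(?P<suffix>[A-Z]))?$"
)


def parse_form_id(text: str, parent: tuple[int, int] | None = None) -> FormCoordinates:
    """Parse a peptide-form identifier like ``"VLVTPGQCN[122-130]"``.

    Coordinates are 1-based inclusive; the sequence length must match the
    residue range. If ``parent`` (the family's full-tryptic range) is given
    the form range must be a sub-interval of it and the terminal flags become
    available on the result.
    """
    m = _FORM_RE.match(text.strip())
    if not m:
        raise QuantTableError(f"malformed form identifier: {text!r}")
    start, end = int(m["start"]), int(m["end"])
    if start > end:
        raise QuantTableError(f"form {text!r}: start {start} > end {end}")
    seq = m["seq"]
    if len(seq) != end - start + 1:
        raise QuantTableError(
            f"form {text!r}: sequence length {len(seq)} does not match "
            f"range [{start}-{end}] ({end - start + 1} residues)"
        )
    ps = pe = None
    if parent is not None:
        ps, pe = parent
        if ps > pe:
            raise QuantTableError(f"parent range [{ps}-{pe}] inverted")
        if start < ps or end > pe:
            raise QuantTableError(
                f"form {text!r} range [{start}-{end}] not within parent [{ps}-{pe}]"
            )
    return FormCoordinates(
        sequence=seq,
        start=start,
        end=end,
        prefix=m["prefix"] or "",
        suffix=m["suffix"] or "",
        parent_start=ps,
        parent_end=pe,
    )


def validate_quant_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a quant table in place; raises QuantTableError naming rows.

    Row numbers in messages are 1-based data rows (header excluded).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise QuantTableError(f"missing columns: {', '.join(missing)}")

    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = df.index[intensity.isna()]
    if len(bad):
        raise QuantTableError(f"non-numeric intensity at row {bad[0] + 1}")
    neg = df.index[intensity < 0]
    if len(neg):
        raise QuantTableError(
            f"negative intensity ({intensity[neg[0]]}) at row {neg[0] + 1}"
        )
    df = df.assign(intensity=intensity.astype(float))

    rep = pd.to_numeric(df["replicate"], errors="coerce")
    bad = df.index[rep.isna() | (rep < 1) | (rep != rep.round())]
    if len(bad):
        raise QuantTableError(f"replicate must be an integer >= 1 at row {bad[0] + 1}")
    df = df.assign(replicate=rep.astype(int))

    bad = df.index[~df["feature_type"].isin(FEATURE_TYPES)]
    if len(bad):
        raise QuantTableError(
            f"unknown feature_type {df['feature_type'][bad[0]]!r} at row {bad[0] + 1}"
        )
    bad = df.index[~df["point"].isin(POINTS)]
    if len(bad):
        raise QuantTableError(
            f"unknown point {df['point'][bad[0]]!r} at row {bad[0] + 1}"
        )

    fam = df["family_id"].fillna("").astype(str)
    form = df["form_id"].fillna("").astype(str)
    bad = df.index[(df["feature_type"] == "peptide") & (fam != "") & (form == "")]
    if len(bad):
        raise QuantTableError(
            f"peptide with family_id but no form_id at row {bad[0] + 1}"
        )

    dup = df.duplicated(subset=KEY)
    if dup.any():
        i = df.index[dup][0]
        raise QuantTableError(
            f"duplicate (feature_id, condition, stage, point, replicate) key "
            f"at row {i + 1}: {tuple(df.loc[i, KEY])}"
        )
    return df


def read_quant_table(path) -> pd.DataFrame:
    """Read and validate a long-format quant CSV. Row count is preserved."""
    df = pd.read_csv(path, dtype={"family_id": str, "form_id": str}, keep_default_na=False)
    df = df.replace({"family_id": {"": ""}, "form_id": {"": ""}})
    n = len(df)
    df = validate_quant_table(df)
    assert len(df) == n
    log.info("read %d quant records from %s", n, path)
    return df


def write_quant_table(df: pd.DataFrame, path) -> None:
    """Write a quant table in the dialect's column order (validates first)."""
    df = validate_quant_table(df.copy())
    df[REQUIRED_COLUMNS].to_csv(path, index=False)
    log.info("wrote %d quant records to %s", len(df), path)
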