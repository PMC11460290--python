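"""Standard DNA Damage (SDD) dialect I/O.

The SDD format is the community interchange format between damage-induction
codes and damage-response models: one record per damage site carrying its
genomic coordinate, spatial position, lesion composition and provenance.
This module fixes a minimal, bit-reproducible dialect of it:

* header as ``key: value`` lines, terminated by ``***EndOfHeader***``;
  unknown keys are preserved verbatim;
* one record per line, comma-separated fields in a fixed order, with
  semicolon-separated sub-fields::

      track_id,time_h,chromosome,bp_position,x;y;z,bd;sb1;sb2,cause,class

* UTF-8, LF line endings; floats serialized with shortest round-trip repr so
  write -> read -> write is byte-identical.

Collections of records are handled as :class:`pandas.DataFrame` objects with
the columns in :data:`RECORD_COLUMNS` (a frame is the canonical in-memory
"sequence of records"; :class:`DamageRecord` is the single-record view).

Conventions: chromosome ids are 1-based, bp offsets 0-based, times in hours,
positions in um relative to the nucleus center.  A DSB is a single record
with strand breaks on both strands; the defining bp separation ("within
10 bp", inclusive) is applied when records are built or re-paired, see
:func:`pair_ssb_records`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HEADER_SENTINEL = "***EndOfHeader***"

RECORD_COLUMNS = [
    "track_id",
    "time_h",
    "chromosome",
    "bp_position",
    "x_um",
    "y_um",
    "z_um",
    "base_damages",
    "breaks_strand1",
    "breaks_strand2",
    "cause",
    "classification",
]

CLASSIFICATIONS = ("BD", "SSB", "DSB")
CAUSES = ("direct", "indirect")


class SDDFormatError(ValueError):
    """Malformed file content (parse-level)."""


class SDDValidationError(ValueError):
    """Structurally valid content violating header/record invariants."""


@dataclass
class SDDHeader:
    """Typed header of the SDD dialect.

    ``extra`` holds unknown header keys verbatim (opaque text, order
    preserved) so foreign metadata survives a round trip.
    """

    source_description: str = ""
    scoring_volume_radius_um: float = 4.65
    chromosome_count: int = 46
    chromosome_lengths: tuple = ()
    direct_threshold_ev: float = 17.5
    indirect_break_probability: float = 0.4
    dsb_bp_separation: int = 10
    time_field_present: bool = False
    dose_or_fluence: str = "dose"
    extra: dict = field(default_factory=dict)

    def validate(self, genome_total_bp: int | None = None) -> None:
        if self.chromosome_count != len(self.chromosome_lengths):
            raise SDDValidationError(
                "chromosome_count does not match number of chromosome lengths"
            )
        if self.direct_threshold_ev <= 0:
            raise SDDValidationError("direct_threshold_ev must be positive")
        if not 0.0 <= self.indirect_break_probability <= 1.0:
            raise SDDValidationError("indirect_break_probability must be in [0, 1]")
        if self.dsb_bp_separation < 1:
            raise SDDValidationError("dsb_bp_separation must be >= 1")
        if self.dose_or_fluence not in ("dose", "fluence"):
            raise SDDValidationError("dose_or_fluence must be 'dose' or 'fluence'")
        if genome_total_bp is not None and sum(self.chromosome_lengths) != genome_total_bp:
            raise SDDValidationError(
                "sum of chromosome lengths does not match paired genome total bp"
            )

    def compatible_with(self, other: "SDDHeader") -> bool:
        """Structural compatibility (everything but free text and extras)."""
        skip = {"source_description", "extra"}
        for f in dc_fields(self):
            if f.name in skip:
                continue
            if getattr(self, f.name) != getattr(other, f.name):
                return False
        return True


@dataclass
class DamageRecord:
    """One damage site (single-record view of a frame row)."""

    track_id: int
    time_h: float
    chromosome: int
    bp_position: int
    position_um: tuple
    base_damages: int
    breaks_strand1: int
    breaks_strand2: int
    cause: str
    classification: str


def empty_records_frame() -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "track_id": pd.Series(dtype=np.int64),
            "time_h": pd.Series(dtype=float),
            "chromosome": pd.Series(dtype=np.int64),
            "bp_position": pd.Series(dtype=np.int64),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "z_um": pd.Series(dtype=float),
            "base_damages": pd.Series(dtype=np.int64),
            "breaks_strand1": pd.Series(dtype=np.int64),
            "breaks_strand2": pd.Series(dtype=np.int64),
            "cause": pd.Series(dtype=pd.CategoricalDtype(CAUSES)),
            "classification": pd.Series(dtype=pd.CategoricalDtype(CLASSIFICATIONS)),
        }
    )
    return frame


def records_to_frame(records: Iterable[DamageRecord]) -> pd.DataFrame:
    records = list(records)
    if not records:
        return empty_records_frame()
    frame = pd.DataFrame(
        {
            "track_id": np.array([r.track_id for r in records], dtype=np.int64),
            "time_h": np.array([r.time_h for r in records], dtype=float),
            "chromosome": np.array([r.chromosome for r in records], dtype=np.int64),
            "bp_position": np.array([r.bp_position for r in records], dtype=np.int64),
            "x_um": np.array([r.position_um[0] for r in records], dtype=float),
            "y_um": np.array([r.position_um[1] for r in records], dtype=float),
            "z_um": np.array([r.position_um[2] for r in records], dtype=float),
            "base_damages": np.array([r.base_damages for r in records], dtype=np.int64),
            "breaks_strand1": np.array([r.breaks_strand1 for r in records], dtype=np.int64),
            "breaks_strand2": np.array([r.breaks_strand2 for r in records], dtype=np.int64),
            "cause": pd.Categorical([r.cause for r in records], categories=CAUSES),
            "classification": pd.Categorical(
                [r.classification for r in records], categories=CLASSIFICATIONS
            ),
        }
    )
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[DamageRecord]:
    return [
        DamageRecord(
            track_id=int(row.track_id),
            time_h=float(row.time_h),
            chromosome=int(row.chromosome),
            bp_position=int(row.bp_position),
            position_um=(float(row.x_um), float(row.y_um), float(row.z_um)),
            base_damages=int(row.base_damages),
            breaks_strand1=int(row.breaks_strand1),
            breaks_strand2=int(row.breaks_strand2),
            cause=str(row.cause),
            classification=str(row.classification),
        )
        for row in frame.itertuples(index=False)
    ]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def validate_records(header: SDDHeader, records) -> None:
    """Check every record invariant against the header.

    Raises :class:`SDDValidationError` naming the first offending record
    index (0-based, file order).
    """
    frame = _as_frame(records)
    header.validate()
    if frame.empty:
        return

    def first_bad(mask, message):
        if mask.any():
            idx = int(np.flatnonzero(np.asarray(mask))[0])
            raise SDDValidationError(f"record {idx}: {message}")

    chrom = frame["chromosome"].to_numpy()
    first_bad((chrom < 1) | (chrom > header.chromosome_count), "chromosome out of range")
    lengths = np.asarray(header.chromosome_lengths, dtype=np.int64)[chrom - 1]
    bp = frame["bp_position"].to_numpy()
    first_bad((bp < 0) | (bp >= lengths), "bp_position out of range for chromosome")

    pos = frame[["x_um", "y_um", "z_um"]].to_numpy()
    r = np.linalg.norm(pos, axis=1)
    first_bad(r > header.scoring_volume_radius_um * (1 + 1e-12),
              "position outside scoring volume")

    bd = frame["base_damages"].to_numpy()
    b1 = frame["breaks_strand1"].to_numpy()
    b2 = frame["breaks_strand2"].to_numpy()
    first_bad((bd < 0) | (b1 < 0) | (b2 < 0), "negative lesion count")
    first_bad(bd + b1 + b2 == 0, "record carries no lesions")

    cls = frame["classification"].astype(str).to_numpy()
    first_bad((cls == "DSB") & ~((b1 > 0) & (b2 > 0)),
              "DSB classification requires breaks on both strands")
    first_bad((cls == "SSB") & (b1 + b2 != 1),
              "SSB classification requires exactly one strand break")
    first_bad((cls == "BD") & (b1 + b2 != 0),
              "BD classification forbids strand breaks")
    first_bad((cls != "DSB") & (b1 > 0) & (b2 > 0),
              "breaks on both strands must be classified DSB")

    t = frame["time_h"].to_numpy()
    first_bad(t < 0, "negative time")
    if header.time_field_present and len(t) > 1:
        dec = np.concatenate([[False], t[1:] < t[:-1]])
        first_bad(dec, "time decreases in file order")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_HEADER_KEYS = [
    ("source_description", str),
    ("scoring_volume_radius_um", float),
    ("chromosome_count", int),
    ("chromosome_lengths", None),  # semicolon-separated ints
    ("direct_threshold_ev", float),
    ("indirect_break_probability", float),
    ("dsb_bp_separation", int),
    ("time_field_present", bool),
    ("dose_or_fluence", str),
]


def _fmt_float(v: float) -> str:
    return repr(float(v))


def _header_lines(header: SDDHeader) -> list[str]:
    lines = []
    for key, typ in _HEADER_KEYS:
        val = getattr(header, key)
        if key == "chromosome_lengths":
            text = ";".join(str(int(v)) for v in val)
        elif typ is float:
            text = _fmt_float(val)
        elif typ is bool:
            text = "1" if val else "0"
        else:
            text = str(val)
        lines.append(f"{key}: {text}")
    for key, text in header.extra.items():
        lines.append(f"{key}: {text}")
    lines.append(HEADER_SENTINEL)
    return lines


def _parse_header(lines: list[str], start_lineno: int = 1) -> SDDHeader:
    known = {k: t for k, t in _HEADER_KEYS}
    values: dict = {}
    extra: dict = {}
    for off, line in enumerate(lines):
        if ":" not in line:
            raise SDDFormatError(
                f"line {start_lineno + off}: header line missing ':' separator"
            )
        key, _, text = line.partition(":")
        key = key.strip()
        text = text.strip()
        if key not in known:
            extra[key] = text
            continue
        typ = known[key]
        try:
            if key == "chromosome_lengths":
                values[key] = tuple(int(v) for v in text.split(";")) if text else ()
            elif typ is float:
                values[key] = float(text)
            elif typ is int:
                values[key] = int(text)
            elif typ is bool:
                values[key] = bool(int(text))
            else:
                values[key] = text
        except ValueError as exc:
            raise SDDFormatError(
                f"line {start_lineno + off}: cannot parse header value for '{key}'"
            ) from exc
    return SDDHeader(extra=extra, **values)


def _record_lines(frame: pd.DataFrame) -> list[str]:
    if frame.empty:
        return []
    track = frame["track_id"].to_numpy()
    time = frame["time_h"].to_numpy()
    chrom = frame["chromosome"].to_numpy()
    bp = frame["bp_position"].to_numpy()
    x = frame["x_um"].to_numpy()
    y = frame["y_um"].to_numpy()
    z = frame["z_um"].to_numpy()
    bd = frame["base_damages"].to_numpy()
    b1 = frame["breaks_strand1"].to_numpy()
    b2 = frame["breaks_strand2"].to_numpy()
    cause = frame["cause"].astype(str).to_numpy()
    cls = frame["classification"].astype(str).to_numpy()
    return [
        f"{int(track[i])},{_fmt_float(time[i])},{int(chrom[i])},{int(bp[i])},"
        f"{_fmt_float(x[i])};{_fmt_float(y[i])};{_fmt_float(z[i])},"
        f"{int(bd[i])};{int(b1[i])};{int(b2[i])},{cause[i]},{cls[i]}"
        for i in range(len(frame))
    ]


def _parse_record_line(line: str, lineno: int) -> tuple:
    parts = line.split(",")
    if len(parts) != 8:
        raise SDDFormatError(f"line {lineno}: expected 8 comma-separated fields")
    try:
        track = int(parts[0])
        time = float(parts[1])
        chrom = int(parts[2])
        bp = int(parts[3])
        xyz = parts[4].split(";")
        lesions = parts[5].split(";")
        if len(xyz) != 3 or len(lesions) != 3:
            raise ValueError("sub-field count")
        x, y, z = (float(v) for v in xyz)
        bd, b1, b2 = (int(v) for v in lesions)
    except ValueError as exc:
        raise SDDFormatError(f"line {lineno}: malformed record field") from exc
    cause, cls = parts[6], parts[7]
    if cause not in CAUSES:
        raise SDDFormatError(f"line {lineno}: unknown cause '{cause}'")
    if cls not in CLASSIFICATIONS:
        raise SDDFormatError(f"line {lineno}: unknown classification '{cls}'")
    return track, time, chrom, bp, x, y, z, bd, b1, b2, cause, cls


def write_sdd(header: SDDHeader, records, destination) -> None:
    """Serialize (header, records) to a path or binary/text stream.

    Records are validated against the header first; a violation raises
    :class:`SDDValidationError` naming the first offending record index.
    """
    frame = _as_frame(records)
    validate_records(header, frame)
    text = "\n".join(_header_lines(header) + _record_lines(frame)) + "\n"
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        with open(destination, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    elif hasattr(destination, "encoding") or isinstance(destination, io.TextIOBase):
        destination.write(text)
    else:
        destination.write(text.encode("utf-8"))


def read_sdd(source) -> tuple[SDDHeader, pd.DataFrame]:
    """Parse an SDD-dialect stream back to ``(header, records frame)``.

    Malformed lines are rejected with a parse error carrying the line
    number; header/record inconsistencies raise a validation error.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        raw = source.read()
        text = raw.decode("utf-8") if isinstance(raw, bytes) else raw
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()

    try:
        sentinel = lines.index(HEADER_SENTINEL)
    except ValueError:
        raise SDDFormatError("missing ***EndOfHeader*** sentinel") from None
    header = _parse_header(lines[:sentinel], start_lineno=1)

    rows = [
        _parse_record_line(line, lineno)
        for lineno, line in enumerate(lines[sentinel + 1 :], start=sentinel + 2)
    ]
    if rows:
        cols = list(zip(*rows))
        frame = pd.DataFrame(
            {
                "track_id": np.array(cols[0], dtype=np.int64),
                "time_h": np.array(cols[1], dtype=float),
                "chromosome": np.array(cols[2], dtype=np.int64),
                "bp_position": np.array(cols[3], dtype=np.int64),
                "x_um": np.array(cols[4], dtype=float),
                "y_um": np.array(cols[5], dtype=float),
                "z_um": np.array(cols[6], dtype=float),
                "base_damages": np.array(cols[7], dtype=np.int64),
                "breaks_strand1": np.array(cols[8], dtype=np.int64),
                "breaks_strand2": np.array(cols[9], dtype=np.int64),
                "cause": pd.Categorical(cols[10], categories=CAUSES),
                "classification": pd.Categorical(cols[11], categories=CLASSIFICATIONS),
            }
        )
    else:
        frame = empty_records_frame()
    validate_records(header, frame)
    return header, frame


# ---------------------------------------------------------------------------
# merging and strand-break pairing
# ---------------------------------------------------------------------------


def merge_records(
    parts: Sequence, headers: Sequence[SDDHeader] | None = None
) -> pd.DataFrame:
    """Concatenate record sets with fresh, unique track ids.

    Track ids are renumbered densely in order of first appearance across
    parts so the merged file can never alias two physical tracks.  Lesion
    counts are conserved exactly; no re-classification happens here (see
    :func:`cellsim.irradiation.recombine_cross_track_dsb`).
    """
    if headers is not None:
        if len(headers) != len(parts):
            raise ValueError("one header per part required")
        for h in headers[1:]:
            if not headers[0].compatible_with(h):
                raise SDDValidationError("incompatible headers in merge")
    frames = [_as_frame(p) for p in parts]
    out = []
    offset = 0
    for frame in frames:
        frame = frame.copy()
        if not frame.empty:
            codes, uniques = pd.factorize(frame["track_id"].to_numpy())
            frame["track_id"] = codes + offset
            offset += len(uniques)
        out.append(frame)
    if not out:
        return empty_records_frame()
    return pd.concat(out, ignore_index=True)


def greedy_break_pairs(
    chrom: np.ndarray,
    bp: np.ndarray,
    strand: np.ndarray,
    track: np.ndarray,
    max_sep: int = 10,
    track_scope: str = "any",
) -> list[tuple[int, int]]:
    """Find opposite-strand single-break pairs within ``max_sep`` bp.

    This is the single implementation of the DSB definition ("two SSBs on
    opposite strands within 10 bp", inclusive) shared by track generation
    (``track_scope='same'``: only breaks of one track pair) and cross-track
    re-evaluation after superposition (``track_scope='different'``).

    Pairing is greedy left-to-right on (chromosome, bp) with each break
    used at most once — deterministic and idempotent.  Returns pairs of
    positional indices into the input arrays, each ``(a, b)`` ordered by
    original index.
    """
    if track_scope not in ("any", "same", "different"):
        raise ValueError("track_scope must be 'any', 'same' or 'different'")
    n = len(bp)
    orig = np.arange(n)
    order = np.lexsort((orig, bp, chrom))
    c, b, s, t, o = chrom[order], bp[order], strand[order], track[order], orig[order]
    used = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        if used[i]:
            continue
        j = i + 1
        while j < n and c[j] == c[i] and b[j] - b[i] <= max_sep:
            ok_track = (
                track_scope == "any"
                or (track_scope == "same" and t[j] == t[i])
                or (track_scope == "different" and t[j] != t[i])
            )
            if not used[j] and s[j] != s[i] and ok_track:
                used[i] = used[j] = True
                a, bb = (o[i], o[j]) if o[i] < o[j] else (o[j], o[i])
                pairs.append((int(a), int(bb)))
                break
            j += 1
    return pairs


def pair_ssb_records(
    frame: pd.DataFrame,
    max_sep: int = 10,
    track_scope: str = "any",
) -> pd.DataFrame:
    """Pair opposite-strand SSB records within ``max_sep`` bp into DSBs.

    The merged DSB record keeps the earlier record's track id, cause and
    spatial position, the *later* arrival time of the two breaks (a DSB
    exists only once both strands are broken) and the smaller bp position.
    Strand-break totals are conserved exactly; non-SSB records pass through
    untouched.  See :func:`greedy_break_pairs` for the pairing rule.
    """
    if frame.empty:
        return frame.copy()
    b1 = frame["breaks_strand1"].to_numpy()
    b2 = frame["breaks_strand2"].to_numpy()
    is_ssb = (frame["classification"].astype(str).to_numpy() == "SSB") & (b1 + b2 == 1)
    idx = np.flatnonzero(is_ssb)
    if len(idx) < 2:
        return frame.copy()

    chrom = frame["chromosome"].to_numpy()[idx]
    bp = frame["bp_position"].to_numpy()[idx]
    strand = np.where(b1[idx] > 0, 1, 2)
    track = frame["track_id"].to_numpy()[idx]
    time = frame["time_h"].to_numpy()[idx]

    pairs = greedy_break_pairs(chrom, bp, strand, track, max_sep, track_scope)
    if not pairs:
        return frame.copy()

    out = frame.reset_index(drop=True).copy()
    drop_rows = []
    for i, j in pairs:  # i, j positional within the SSB subset; idx maps back
        a, b = int(idx[i]), int(idx[j])
        out.loc[a, "bp_position"] = int(min(bp[i], bp[j]))
        out.loc[a, "time_h"] = float(max(time[i], time[j]))
        out.loc[a, "breaks_strand1"] = 1
        out.loc[a, "breaks_strand2"] = 1
        out.loc[a, "classification"] = "DSB"
        drop_rows.append(b)
    out = out.drop(index=drop_rows).reset_index(drop=True)
    return out
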