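"""Readers/writers for every external format the pipeline touches, plus the
mapping of reference-sequence variant positions onto standardized models.

Formats handled: tab-separated variant tables, ASCII PSSM profiles
(PSIBLAST ``-out_ascii_pssm`` dialect), whitespace-delimited score files
(both the leading ``SCORE:`` token dialect and bare tables), per-residue
accessible-surface tables, PDB models, and the tab-separated predictions
output.  Serializers round-trip bit-exactly with the parsers so synthetic
fixtures can exercise the real parsing path.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

from Bio.PDB import PDBParser

from .config import PSSM_ALPHABET, STANDARD_AAS, THREE_TO_ONE

logger = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"
VALID_LABELS = ("deleterious", "neutral", "unknown")


class FormatError(ValueError):
    """Malformed input file (wrong layout, field counts, or dialect)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


class ChainError(ValueError):
    """Requested chain absent from the structural model."""


class MismatchError(ValueError):
    """Model residue identity disagrees with the variant's native amino acid;
    signals a wrong model or wrong isoform, distinct from UNMAPPED."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """One amino-acid substitution in one protein."""

    protein_id: str
    position: int          # 1-based on the reference sequence
    native_aa: str
    variant_aa: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.native_aa not in STANDARD_AAS:
            raise ValidationError(f"non-standard native amino acid {self.native_aa!r}")
        if self.variant_aa not in STANDARD_AAS:
            raise ValidationError(f"non-standard variant amino acid {self.variant_aa!r}")
        if self.native_aa == self.variant_aa:
            raise ValidationError(
                f"identity substitution {self.native_aa}{self.position}{self.variant_aa}"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.label not in VALID_LABELS:
            raise ValidationError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def name(self) -> str:
        return f"{self.native_aa}{self.position}{self.variant_aa}"


@dataclass(frozen=True)
class SequenceProfile:
    """Per-position 20-column log-odds profile with information content."""

    protein_id: str
    sequence: str
    log_odds: tuple[tuple[int, ...], ...]      # one 20-tuple per position
    info_content: tuple[float, ...]            # bits, >= 0
    percentages: tuple[tuple[int, ...], ...] = ()   # optional observed-frequency columns
    weights: tuple[float, ...] = ()                 # optional relative-weight column

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (len(self.log_odds) == len(self.info_content) == n):
            raise ValidationError("profile rows must match sequence length")
        if any(len(row) != 20 for row in self.log_odds):
            raise ValidationError("every log-odds row needs exactly 20 entries")

    def __len__(self) -> int:
        return len(self.sequence)

    def log_odds_of(self, position: int, aa: str) -> int:
        """Log-odds of amino acid ``aa`` at 1-based ``position``."""
        return self.log_odds[position - 1][PSSM_ALPHABET.index(aa)]


@dataclass(frozen=True)
class ScoreTable:
    """Per-decoy, per-score-term table from one refinement protocol."""

    protocol: str                              # "ddg_monomer" | "fast_relax"
    terms: tuple[str, ...]
    decoys: tuple[tuple[float, ...], ...]      # one row per decoy, term order
    descriptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.decoys:
            raise FormatError("score table must contain at least one decoy")
        if any(len(row) != len(self.terms) for row in self.decoys):
            raise FormatError("every decoy must cover the full score-term set")
        if not self.descriptions:
            object.__setattr__(self, "descriptions", tuple(
                f"decoy_{i:04d}" for i in range(1, len(self.decoys) + 1)))
        elif len(self.descriptions) != len(self.decoys):
            raise FormatError("one description tag required per decoy")

    @property
    def n_decoys(self) -> int:
        return len(self.decoys)

    def column(self, term: str) -> tuple[float, ...]:
        try:
            j = self.terms.index(term)
        except ValueError:
            raise KeyError(f"score term {term!r} absent from table") from None
        return tuple(row[j] for row in self.decoys)


@dataclass(frozen=True)
class Residue:
    number: int
    amino_acid: str
    atoms: tuple[tuple[str, float, float, float], ...]


@dataclass(frozen=True)
class CleanModel:
    """A standardized single-chain protein model.

    ``offset_map`` sends 1-based reference-sequence positions to model
    residue numbers; when no reference was supplied it is the identity on
    the model's own numbering.
    """

    model_id: str
    chain: str
    residues: tuple[Residue, ...]
    offset_map: dict[int, int] = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def residue_by_number(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"no residue numbered {number} in model {self.model_id}")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ("protein", "position", "native", "variant")


def read_variant_table(path) -> list[VariantSpec]:
    """Read a tab-separated variant table.

    Required columns: protein, position, native, variant; optional: label.
    Rows violating the substitution invariants are rejected and reported
    (with their 1-based data-row numbers) through the module logger.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty variant table")
    header = lines[0].split("\t")
    for col in _VARIANT_COLUMNS:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in header}
    has_label = "label" in idx

    variants: list[VariantSpec] = []
    for row_no, line in enumerate(lines[1:], start=1):
        fields = line.split("\t")
        if len(fields) != len(header):
            logger.warning("row %d rejected: %d fields, expected %d",
                           row_no, len(fields), len(header))
            continue
        try:
            variants.append(VariantSpec(
                protein_id=fields[idx["protein"]],
                position=int(fields[idx["position"]]),
                native_aa=fields[idx["native"]],
                variant_aa=fields[idx["variant"]],
                label=fields[idx["label"]] if has_label else "unknown",
            ))
        except (ValidationError, ValueError) as exc:
            logger.warning("row %d rejected: %s", row_no, exc)
    return variants


def write_variant_table(variants, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tposition\tnative\tvariant\tlabel\n")
        for v in variants:
            fh.write(f"{v.protein_id}\t{v.position}\t{v.native_aa}\t{v.variant_aa}\t{v.label}\n")


# ---------------------------------------------------------------------------
# ASCII PSSM profiles
# ---------------------------------------------------------------------------


def parse_pssm(text: str, protein_id: str = "") -> SequenceProfile:
    """Parse an ASCII PSSM (PSIBLAST ``-out_ascii_pssm`` layout).

    Each position row carries: 1-based index, native residue, 20 log-odds
    integers, 20 observed-percentage integers, information content and
    relative weight — 42 numeric fields after the residue letter.
    """
    sequence: list[str] = []
    log_odds: list[tuple[int, ...]] = []
    percentages: list[tuple[int, ...]] = []
    info: list[float] = []
    weights: list[float] = []

    expected_index = 1
    for line in text.splitlines():
        fields = line.split()
        # Position rows start "<int> <AA> ..."; anything else is header/footer.
        if len(fields) < 2 or not fields[0].isdigit() or len(fields[1]) != 1:
            continue
        numeric = fields[2:]
        if len(numeric) != 42:
            raise FormatError(
                f"PSSM row {fields[0]}: {len(numeric)} numeric fields, expected 42"
            )
        if int(fields[0]) != expected_index:
            raise FormatError(
                f"PSSM rows out of order: got index {fields[0]}, expected {expected_index}"
            )
        expected_index += 1
        sequence.append(fields[1])
        try:
            log_odds.append(tuple(int(x) for x in numeric[:20]))
            percentages.append(tuple(int(x) for x in numeric[20:40]))
            info.append(float(numeric[40]))
            weights.append(float(numeric[41]))
        except ValueError as exc:
            raise FormatError(f"PSSM row {fields[0]}: non-numeric cell ({exc})") from None

    if not sequence:
        raise FormatError("PSSM contains no position rows")
    return SequenceProfile(
        protein_id=protein_id,
        sequence="".join(sequence),
        log_odds=tuple(log_odds),
        info_content=tuple(info),
        percentages=tuple(percentages),
        weights=tuple(weights),
    )


def write_pssm(profile: SequenceProfile, path=None) -> str:
    """Serialize a profile to the ASCII PSSM dialect; returns the text."""
    out = io.StringIO()
    out.write("\nLast position-specific scoring matrix computed\n")
    header_aas = "  ".join(PSSM_ALPHABET)
    out.write(f"            {header_aas}   {header_aas}\n")
    n = len(profile)
    pct = profile.percentages or tuple((0,) * 20 for _ in range(n))
    wts = profile.weights or tuple(0.0 for _ in range(n))
    for i in range(n):
        lo = " ".join(f"{v:3d}" for v in profile.log_odds[i])
        pc = " ".join(f"{v:3d}" for v in pct[i])
        out.write(f"{i + 1:5d} {profile.sequence[i]}  {lo}  {pc}  "
                  f"{profile.info_content[i]:.2f} {wts[i]:.2f}\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Score files
# ---------------------------------------------------------------------------


def parse_rosetta_scorefile(text: str, protocol: str) -> ScoreTable:
    """Parse a whitespace-delimited score file into a ScoreTable.

    Accepts both the leading ``SCORE:`` token dialect and bare whitespace
    tables.  A trailing ``description`` column, when present in the header,
    is kept as the per-decoy tag rather than a score term.
    """
    if protocol not in ("ddg_monomer", "fast_relax"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rows: list[list[str]] = []
    for line in text.splitlines():
        if line.startswith("SEQUENCE:") or not line.strip():
            continue
        fields = line.split()
        if fields and fields[0] == "SCORE:":
            fields = fields[1:]
        if fields:
            rows.append(fields)
    if not rows:
        raise FormatError("score file has no header line")
    header = rows[0]
    has_description = header and header[-1] == "description"
    terms = tuple(header[:-1] if has_description else header)
    if not terms:
        raise FormatError("score file header names no score terms")

    decoys: list[tuple[float, ...]] = []
    tags: list[str] = []
    for i, fields in enumerate(rows[1:], start=1):
        if len(fields) != len(header):
            raise FormatError(
                f"decoy line {i}: {len(fields)} fields, expected {len(header)}"
            )
        values = fields[:-1] if has_description else fields
        try:
            decoys.append(tuple(float(x) for x in values))
        except ValueError as exc:
            raise FormatError(f"decoy line {i}: non-numeric cell ({exc})") from None
        tags.append(fields[-1] if has_description else f"decoy_{i:04d}")
    if not decoys:
        raise FormatError("score file contains zero decoys")
    return ScoreTable(protocol=protocol, terms=terms, decoys=tuple(decoys),
                      descriptions=tuple(tags))


def write_scorefile(table: ScoreTable, path=None, dialect: str = "score") -> str:
    """Serialize a ScoreTable; ``dialect`` is "score" (SCORE: tokens) or "bare"."""
    prefix = "SCORE: " if dialect == "score" else ""
    out = io.StringIO()
    out.write(prefix + " ".join(table.terms) + " description\n")
    tags = table.descriptions or tuple(f"decoy_{i:04d}" for i in range(1, table.n_decoys + 1))
    for row, tag in zip(table.decoys, tags):
        cells = " ".join(repr(v) for v in row)
        out.write(f"{prefix}{cells} {tag}\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Per-residue accessible-surface tables
# ---------------------------------------------------------------------------


def parse_probe_output(text: str) -> dict[int, float]:
    """Parse a per-residue accessible-surface table.

    Expected rows: ``<residue_number> [<residue_name>] <area>``; ``#``
    comment lines ignored.  Returns residue number -> area.
    """
    areas: dict[int, float] = {}
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise FormatError(f"surface row needs >= 2 fields: {line!r}")
        try:
            areas[int(fields[0])] = float(fields[-1])
        except ValueError as exc:
            raise FormatError(f"surface row {line!r}: {exc}") from None
    return areas


def write_probe_output(areas: dict[int, float], path=None) -> str:
    out = io.StringIO()
    out.write("# residue area\n")
    for num in sorted(areas):
        out.write(f"{num} {areas[num]!r}\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Structural models
# ---------------------------------------------------------------------------


def standardize_structure(pdb_text: str, chain: str | None = None,
                          reference_sequence: str | None = None,
                          model_id: str = "model") -> CleanModel:
    """Standardize a PDB model to a single clean protein chain.

    Keeps the requested chain (else the alphabetically first protein chain)
    and drops heteroatom ligands, metals, waters and non-standard residues.
    When ``reference_sequence`` is given, the retained residue sequence is
    placed on it by ungapped sliding-window alignment to build the
    reference-position -> model-residue-number offset map; otherwise the
    map is the identity on model numbering.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(model_id, io.StringIO(pdb_text))
    model = next(structure.get_models())

    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues = []
        for res in ch:
            hetflag = res.id[0]
            if hetflag != " ":
                continue                      # HETATM: ligand/metal/water
            resname = res.get_resname().strip()
            if resname not in THREE_TO_ONE:
                continue                      # non-standard amino acid
            atoms = tuple(
                (a.get_name(), float(a.coord[0]), float(a.coord[1]), float(a.coord[2]))
                for a in res
            )
            residues.append(Residue(number=res.id[1],
                                    amino_acid=THREE_TO_ONE[resname],
                                    atoms=atoms))
        if residues:
            chains[ch.id] = residues

    if chain is not None:
        if chain not in chains:
            raise ChainError(f"chain {chain!r} absent (found {sorted(chains)})")
        chosen = chain
    else:
        if not chains:
            raise ValidationError("no standard protein residues remain")
        chosen = sorted(chains)[0]
    residues = tuple(chains[chosen])

    if reference_sequence is not None:
        offset_map = _align_ungapped(residues, reference_sequence)
    else:
        offset_map = {r.number: r.number for r in residues}
    return CleanModel(model_id=model_id, chain=chosen, residues=residues,
                      offset_map=offset_map)


def _align_ungapped(residues: tuple[Residue, ...], reference: str) -> dict[int, int]:
    """Best ungapped placement of the model sequence on the reference.

    Slides the model sequence over the reference, scores identities, and
    maps each aligned reference position to the corresponding model residue
    number.  Ties go to the left-most placement.
    """
    model_seq = "".join(r.amino_acid for r in residues)
    m, n = len(model_seq), len(reference)
    best_start, best_score = 0, -1
    for start in range(-(m - 1), n):
        score = sum(
            1
            for i in range(m)
            if 0 <= start + i < n and model_seq[i] == reference[start + i]
        )
        if score > best_score:
            best_start, best_score = start, score
    offset_map = {}
    for i, res in enumerate(residues):
        ref_pos = best_start + i + 1          # 1-based
        if 1 <= ref_pos <= n:
            offset_map[ref_pos] = res.number
    return offset_map


def map_variant_to_model(variant: VariantSpec, model: CleanModel):
    """Model residue number for a variant, or UNMAPPED when outside coverage.

    Raises MismatchError when the mapped model residue's amino acid differs
    from the variant's native amino acid (wrong model or isoform).
    """
    if variant.position not in model.offset_map:
        return UNMAPPED
    number = model.offset_map[variant.position]
    residue = model.residue_by_number(number)
    if residue.amino_acid != variant.native_aa:
        raise MismatchError(
            f"{variant.protein_id} {variant.name}: model residue {number} is "
            f"{residue.amino_acid}, expected {variant.native_aa}"
        )
    return number


# ---------------------------------------------------------------------------
# Predictions output
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ("protein", "position", "native", "variant", "score",
                      "label", "top_structural_terms", "interpretation")


def write_predictions(predictions, path, provenance: dict | None = None) -> None:
    """Write prediction rows as TSV; scores printed with 3 decimals.

    ``predictions`` is an iterable of mappings (or objects with an
    ``as_row`` method) providing the PREDICTION_COLUMNS fields.  Optional
    provenance key/values are written as leading ``#`` comment lines.
    """
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for p in predictions:
            row = p.as_row() if hasattr(p, "as_row") else dict(p)
            fh.write("\t".join([
                str(row["protein"]), str(row["position"]), row["native"],
                row["variant"], f"{float(row['score']):.3f}", row["label"],
                row.get("top_structural_terms", ""), row.get("interpretation", ""),
            ]) + "\n")


def read_predictions(path) -> list[dict]:
    """Read back a predictions TSV (inverse of write_predictions)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty predictions file")
    header = lines[0].split("\t")
    if tuple(header) != PREDICTION_COLUMNS:
        raise FormatError(f"{path}: unexpected header {header}")
    out = []
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}: bad row {line!r}")
        rec = dict(zip(header, fields))
        rec["position"] = int(rec["position"])
        rec["score"] = float(rec["score"])
        out.append(rec)
    return out
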