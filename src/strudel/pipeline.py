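"""End-to-end orchestration: features -> classify -> interpret -> report.

The pipeline reads a variant table, looks up each protein's sequence
profile and (optionally) structural model plus refinement score files,
assembles the 106-feature vector, routes each variant to the combined or
the sequence-only classifier depending on whether it could be placed on a
structural model, and writes a predictions TSV with an automated physical
interpretation per variant.  Training runs stability selection, fits the
combined and sequence-only models, and reports protein-level split
performance.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np

from . import config
from .classifier import (LabeledDataset, MissingFeatureError, load_model, predict,
                         save_model, stability_select, train)
from .evaluation import average_curves, protein_level_splits, roc_pr
from .formats_io import (MismatchError, UNMAPPED, map_variant_to_model,
                         parse_pssm, parse_rosetta_scorefile,
                         read_variant_table, standardize_structure,
                         write_predictions)
from .interpretation import categorize_contributions, top_structural_terms
from .sequence_features import compute_sequence_features
from .structure_features import (EnsemblePair, assemble_feature_vector,
                                 compute_ddg_features, compute_relax_features,
                                 surface_area_feature)
from .synthetic import SignalSpec, generate_labeled_dataset, generate_score_ensembles

logger = logging.getLogger(__name__)

MANIFEST_VERSION = 1

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_RUNTIME = 3


@dataclass
class RunConfig:
    """Flat run configuration; serializable as key=value lines."""

    variants: str = ""
    profiles_dir: str = ""
    models_dir: str = ""
    scores_dir: str = ""
    backend: str = "disk"            # "disk" | "synthetic"
    mode: str = "combined"
    model_path: str = "strudel.model"
    out: str = "predictions.tsv"
    feature_table: str = ""
    n_splits: int = config.N_SPLITS
    n_decoys: int = config.DEFAULT_RELAX_DECOYS
    seed: int = 0
    verbosity: str = "info"

    def digest(self) -> str:
        payload = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.digest(), "seed": self.seed,
                "manifest_version": MANIFEST_VERSION}


def load_config(path) -> RunConfig:
    """Read a flat key=value config file (``#`` comments allowed)."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line {line!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    cfg = RunConfig()
    for key, val in values.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        setattr(cfg, key, type(current)(val) if not isinstance(current, str) else val)
    return cfg


# ---------------------------------------------------------------------------
# Feature assembly for one variant
# ---------------------------------------------------------------------------


def _derived_seed(base_seed: int, *parts) -> int:
    h = hashlib.sha256(("|".join(map(str, parts)) + f"|{base_seed}").encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def _disk_backend(cfg: RunConfig, variant, protocol: str) -> EnsemblePair:
    base = os.path.join(cfg.scores_dir, f"{variant.protein_id}.{variant.name}.{protocol}")
    with open(base + ".native.sc") as fh:
        native = parse_rosetta_scorefile(fh.read(), protocol)
    with open(base + ".variant.sc") as fh:
        var = parse_rosetta_scorefile(fh.read(), protocol)
    return EnsemblePair(native=native, variant=var, protocol=protocol)


def _synthetic_backend(cfg: RunConfig, variant, protocol: str) -> EnsemblePair:
    seed = _derived_seed(cfg.seed, variant.protein_id, variant.name, protocol)
    n = cfg.n_decoys if protocol == "fast_relax" else max(cfg.n_decoys // 2, 5)
    return generate_score_ensembles(n_decoys=n, seed=seed, protocol=protocol)


BACKENDS = {"disk": _disk_backend, "synthetic": _synthetic_backend}


def compute_variant_features(cfg: RunConfig, variant, profile, model=None,
                             probe_text: str | None = None):
    """Assemble the feature vector for one variant.

    Returns ``(FeatureVector, routing)`` where routing is "combined",
    "sequence_only" (no model / outside coverage) or "mismatch" (model
    residue disagrees with the native amino acid; structure untrusted).
    """
    seq = compute_sequence_features(profile, variant)
    routing = "combined"
    residue = UNMAPPED
    if model is None:
        routing = "sequence_only"
    else:
        try:
            residue = map_variant_to_model(variant, model)
        except MismatchError as exc:
            logger.error("%s", exc)
            routing = "mismatch"
        else:
            if residue == UNMAPPED:
                routing = "sequence_only"

    if routing != "combined":
        return assemble_feature_vector(seq, available=False), routing

    backend = BACKENDS[cfg.backend]
    ddg = compute_ddg_features(backend(cfg, variant, "ddg_monomer"))
    relax = compute_relax_features(backend(cfg, variant, "fast_relax"))
    if probe_text is not None:
        surface = surface_area_feature(probe_text, residue)
    elif cfg.backend == "synthetic":
        rng = np.random.default_rng(_derived_seed(cfg.seed, variant.protein_id,
                                                  variant.name, "probe"))
        surface = round(float(rng.uniform(0.0, 150.0)), 1)
    else:
        raise FileNotFoundError(
            f"no surface table for {variant.protein_id} {variant.name}")
    fv = assemble_feature_vector(seq, ddg=ddg, relax=relax, surface=surface,
                                 available=True)
    return fv, routing


def _load_protein_inputs(cfg: RunConfig, protein_id: str):
    pssm_path = os.path.join(cfg.profiles_dir, f"{protein_id}.pssm")
    with open(pssm_path) as fh:
        profile = parse_pssm(fh.read(), protein_id=protein_id)
    model = None
    probe_text = None
    pdb_path = os.path.join(cfg.models_dir, f"{protein_id}.pdb") if cfg.models_dir else ""
    if pdb_path and os.path.exists(pdb_path):
        with open(pdb_path) as fh:
            model = standardize_structure(fh.read(),
                                          reference_sequence=profile.sequence,
                                          model_id=protein_id)
    probe_path = os.path.join(cfg.scores_dir, f"{protein_id}.probe.txt") if cfg.scores_dir else ""
    if probe_path and os.path.exists(probe_path):
        with open(probe_path) as fh:
            probe_text = fh.read()
    return profile, model, probe_text


# ---------------------------------------------------------------------------
# Predict
# ---------------------------------------------------------------------------


def run_predict(cfg: RunConfig) -> dict:
    """Score every variant in the input table and write the predictions TSV.

    Variants that cannot be placed on a structural model are scored by the
    sequence-only model and flagged; every input variant appears exactly
    once in the output.  Returns a routing summary.
    """
    variants = read_variant_table(cfg.variants)
    combined = load_model(cfg.model_path)
    seq_model_path = cfg.model_path + ".seq"
    seq_model = load_model(seq_model_path) if os.path.exists(seq_model_path) else None

    rows = []
    summary = {"combined": 0, "sequence_only": 0, "mismatch": 0}
    cache: dict[str, tuple] = {}
    for v in variants:
        if v.protein_id not in cache:
            cache[v.protein_id] = _load_protein_inputs(cfg, v.protein_id)
        profile, model, probe_text = cache[v.protein_id]
        fv, routing = compute_variant_features(cfg, v, profile, model, probe_text)
        try:
            if routing == "combined":
                pred = predict(combined, fv, variant=v)
            else:
                if seq_model is None:
                    raise MissingFeatureError(
                        f"no sequence-only model at {seq_model_path} for "
                        f"unmapped variant {v.protein_id} {v.name}")
                pred = predict(seq_model, fv, variant=v)
        except MissingFeatureError:
            if seq_model is None:
                raise
            pred = predict(seq_model, fv, variant=v)
            routing = "sequence_only"
        summary[routing] += 1
        logger.info("%s %s routed to %s (score %.3f)",
                    v.protein_id, v.name, pred.mode, pred.score)
        report = categorize_contributions(pred)
        note = report.narrative
        if routing == "mismatch":
            note += " [model mismatch: structure ignored]"
        elif routing == "sequence_only":
            note += " [no structural model]"
        rows.append({
            "protein": v.protein_id, "position": v.position,
            "native": v.native_aa, "variant": v.variant_aa,
            "score": pred.score, "label": pred.label,
            "top_structural_terms": top_structural_terms(pred),
            "interpretation": note,
        })
    write_predictions(rows, cfg.out, provenance=cfg.provenance())
    logger.info("routing summary: %s", summary)
    return summary


# ---------------------------------------------------------------------------
# Train
# ---------------------------------------------------------------------------


def run_train(cfg: RunConfig, dataset: LabeledDataset | None = None) -> dict:
    """Stability selection + final fits + protein-level split evaluation.

    ``dataset`` may be passed directly (e.g. synthetic); otherwise it is
    read from ``cfg.feature_table``.  Writes the combined model to
    ``cfg.model_path``, the sequence-only model alongside it (suffix
    ``.seq``) and a split-performance summary; returns the summary.
    """
    if dataset is None:
        if not cfg.feature_table:
            raise ValueError("run_train needs a dataset or cfg.feature_table")
        dataset = read_feature_table(cfg.feature_table)

    selected = stability_select(dataset, seed=cfg.seed)
    if not selected:
        raise ValueError("stability selection returned no features")
    combined = train(dataset, selected=selected, mode="combined")
    seq_model = train(dataset, mode="sequence_only")
    save_model(combined, cfg.model_path)
    save_model(seq_model, cfg.model_path + ".seq")

    curves = []
    if cfg.n_splits >= 1:
        splits = protein_level_splits(dataset, n_splits=cfg.n_splits, seed=cfg.seed)
        for train_idx, test_idx in splits:
            fold_model = train(dataset.subset(train_idx), selected=selected,
                               mode="combined")
            test = dataset.subset(test_idx)
            scores = [predict(fold_model, dict(zip(test.feature_names, row))).score
                      for row in test.features]
            curves.append(roc_pr(scores, test.labels))
    if len(curves) > 1:
        avg = average_curves(curves)
        auroc, aupr = avg.auroc, avg.aupr
    elif curves:
        auroc, aupr = curves[0].auroc, curves[0].aupr
    else:
        auroc = aupr = float("nan")

    summary = {"selected": selected, "n_splits": len(curves),
               "auroc": auroc, "aupr": aupr}
    report_path = cfg.model_path + ".report.tsv"
    with open(report_path, "w") as fh:
        for key, value in cfg.provenance().items():
            fh.write(f"# {key}={value}\n")
        fh.write("metric\tvalue\n")
        fh.write(f"n_selected\t{len(selected)}\n")
        fh.write(f"selected\t{','.join(selected)}\n")
        fh.write(f"n_splits\t{len(curves)}\n")
        fh.write(f"auroc\t{auroc:.4f}\n")
        fh.write(f"aupr\t{aupr:.4f}\n")
    logger.info("training summary: AUROC %.3f AUPR %.3f (%d splits)",
                auroc, aupr, len(curves))
    return summary


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def write_feature_table(dataset: LabeledDataset, path) -> None:
    names = dataset.feature_names
    with open(path, "w") as fh:
        fh.write("protein\tposition\tnative\tvariant\tlabel\t" + "\t".join(names) + "\n")
        for v, row in zip(dataset.variants, dataset.features):
            cells = "\t".join(repr(float(x)) for x in row)
            fh.write(f"{v.protein_id}\t{v.position}\t{v.native_aa}\t"
                     f"{v.variant_aa}\t{v.label}\t{cells}\n")


def read_feature_table(path) -> LabeledDataset:
    from .formats_io import FormatError, VariantSpec
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty feature table")
    header = lines[0].split("\t")
    meta = ("protein", "position", "native", "variant", "label")
    if tuple(header[:5]) != meta:
        raise FormatError(f"{path}: feature table must start with columns {meta}")
    names = tuple(header[5:])
    variants, rows = [], []
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}: bad row {fields[:5]}")
        variants.append(VariantSpec(protein_id=fields[0], position=int(fields[1]),
                                    native_aa=fields[2], variant_aa=fields[3],
                                    label=fields[4]))
        rows.append([float(x) for x in fields[5:]])
    return LabeledDataset(variants=variants, features=np.asarray(rows),
                          feature_names=names)


def simulate_dataset(cfg: RunConfig, spec: SignalSpec | None = None) -> LabeledDataset:
    """Generate a planted-signal dataset under the run's seed."""
    if spec is None:
        spec = SignalSpec(seed=cfg.seed)
    return generate_labeled_dataset(spec)
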