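"""Synthetic expression compendia with planted co-expression modules.

Every downstream stage is testable against known ground truth: module genes
share a latent factor (giving a closed-form target for their pairwise
correlation), modules may be active only in arrays matching a metadata
selector (emulating condition-dependent clusters such as fruit-specific
modules), arrays carry additive scale offsets, and a matching GO annotation
table plants enriched terms on module genes over a uniform annotated
background.

Under the single-factor model  x = a * z + eps,  z ~ N(0, 1),
eps ~ N(0, sigma^2), the pairwise correlation between two module genes is
r = a^2 / (a^2 + sigma^2); the loading is solved from the requested r as
a = sigma * sqrt(r / (1 - r)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import METADATA_FIELDS, AnnotationSet, ExpressionMatrix


@dataclass
class ModuleSpec:
    """A planted co-expressed module.

    ``active_conditions`` is a metadata selector (field -> value); the module
    co-varies only in matching arrays and is flat noise elsewhere.  ``None``
    makes it condition-independent.  Condition-restricted modules are also
    raised by ``active_offset`` (log2 units) in their active arrays,
    emulating tissue-specific induction; 4.0 corresponds to a 16-fold
    up-regulation, typical of strongly tissue-specific transcripts.
    ``planted_terms`` are attached to a fraction ``annotated_fraction`` of
    the module's genes.
    """

    module_id: str
    size: int = 15
    within_correlation: float = 0.9
    active_conditions: dict[str, str] | None = None
    base_expression: float = 8.0
    amplitude: float = 1.0
    active_offset: float = 4.0
    planted_terms: tuple[str, ...] = ()
    annotated_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("module size must be >= 3")
        if not 0 < self.within_correlation < 1:
            raise ValueError(
                f"within_correlation must be in (0, 1), got {self.within_correlation}"
            )


@dataclass
class GroundTruth:
    assignment: dict[str, str | None]  # probeset -> module id (None = noise gene)
    module_arrays: dict[str, list[str]]  # module id -> arrays where it is active
    planted_terms: dict[str, list[str]]  # module id -> GO term ids

    def module_members(self, module_id: str) -> list[str]:
        return [p for p, m in self.assignment.items() if m == module_id]

    def to_json(self) -> str:
        return json.dumps(
            {
                "assignment": self.assignment,
                "module_arrays": self.module_arrays,
                "planted_terms": self.planted_terms,
            },
            indent=2,
        )


#: default label vocabulary for the four metadata fields
DEFAULT_DESIGN = {
    "subspecies": ("sweet_orange", "mandarin", "lemon"),
    "organ": ("fruit", "leaf", "root", "flower"),
    "experiment_type": ("development", "biotic_stress", "abiotic_stress"),
}


def default_metadata(n_arrays: int) -> pd.DataFrame:
    """Deterministic round-robin assignment of metadata labels to arrays."""
    rows = []
    for i in range(n_arrays):
        rows.append(
            {
                "array_id": f"A{i + 1:04d}",
                "subspecies": DEFAULT_DESIGN["subspecies"][i % 3],
                "organ": DEFAULT_DESIGN["organ"][i % 4],
                "experiment_type": DEFAULT_DESIGN["experiment_type"][i % 3],
                "description": f"synthetic array {i + 1}",
            }
        )
    return pd.DataFrame(rows).set_index("array_id")


def generate(
    n_genes: int = 300,
    n_arrays: int = 40,
    metadata_design: pd.DataFrame | None = None,
    modules: tuple[ModuleSpec, ...] | list[ModuleSpec] = (),
    noise_sd: float = 1.0,
    array_effect_sd: float = 0.25,
    seed: int | None = None,
    n_background_terms: int = 20,
    background_term_size: int = 10,
) -> tuple[ExpressionMatrix, pd.DataFrame, AnnotationSet, GroundTruth]:
    """Generate a compendium, its metadata, annotations and ground truth.

    Module genes occupy the first rows in ModuleSpec list order; everything else is
    independent Gaussian noise around ``base_expression``.  Per-array
    additive offsets (scale effects surviving normalization) are drawn with
    ``array_effect_sd``.  Background annotations attach
    ``n_background_terms`` terms to ``background_term_size`` random genes
    each.  Fully deterministic given ``seed``.
    """
    modules = list(modules)
    total = sum(m.size for m in modules)
    if total > n_genes:
        raise ValueError(f"module sizes sum to {total} > n_genes = {n_genes}")
    rng = np.random.default_rng(seed)
    metadata = metadata_design if metadata_design is not None else default_metadata(n_arrays)
    if len(metadata) != n_arrays:
        raise ValueError("metadata_design does not match n_arrays")
    for fld in METADATA_FIELDS:
        if fld not in metadata.columns:
            raise ValueError(f"metadata_design lacks field {fld!r}")
    array_ids = list(metadata.index)
    width = max(5, len(str(n_genes)))
    probeset_ids = [f"PS{i + 1:0{width}d}" for i in range(n_genes)]

    values = rng.normal(0.0, noise_sd, size=(n_genes, n_arrays))
    assignment: dict[str, str | None] = {p: None for p in probeset_ids}
    module_arrays: dict[str, list[str]] = {}
    row = 0
    for spec in modules:
        if spec.active_conditions:
            active = np.array(
                [
                    all(metadata.at[a, f] == v for f, v in spec.active_conditions.items())
                    for a in array_ids
                ]
            )
            if active.sum() < 3:
                raise ValueError(
                    f"module {spec.module_id}: selector {spec.active_conditions!r} "
                    f"matches {int(active.sum())} arrays (< 3)"
                )
        else:
            active = np.ones(n_arrays, dtype=bool)
        # loading solved so that r = (coeff*amplitude)^2 / ((coeff*amplitude)^2 + noise_sd^2):
        # amplitude only reparameterizes the latent scale, the target r always wins
        r = spec.within_correlation
        coeff = (noise_sd / spec.amplitude) * np.sqrt(r / (1.0 - r))
        latent = rng.normal(0.0, spec.amplitude, size=int(active.sum()))
        genes = slice(row, row + spec.size)
        values[genes, :] += spec.base_expression
        values[genes, active] += coeff * latent
        if spec.active_conditions:
            values[genes, active] += spec.active_offset
        for g in range(row, row + spec.size):
            assignment[probeset_ids[g]] = spec.module_id
        module_arrays[spec.module_id] = [a for a, act in zip(array_ids, active) if act]
        row += spec.size
    values[row:, :] += 8.0  # noise-gene baseline
    values += rng.normal(0.0, array_effect_sd, size=(1, n_arrays))

    associations: dict[str, set[tuple[str, str]]] = {p: set() for p in probeset_ids}
    term_names: dict[str, str] = {}
    planted: dict[str, list[str]] = {}
    row = 0
    for spec in modules:
        planted[spec.module_id] = list(spec.planted_terms)
        n_annot = int(np.ceil(spec.annotated_fraction * spec.size))
        for term in spec.planted_terms:
            for g in range(row, row + n_annot):
                associations[probeset_ids[g]].add((term, "BP"))
            term_names[term] = f"planted process of module {spec.module_id}"
        row += spec.size
    for t in range(n_background_terms):
        term = f"GO:9{t + 1:06d}"
        term_names[term] = f"background process {t + 1}"
        genes = rng.choice(n_genes, size=min(background_term_size, n_genes), replace=False)
        for g in genes:
            associations[probeset_ids[g]].add((term, "BP"))

    matrix = ExpressionMatrix(probeset_ids, array_ids, values)
    annset = AnnotationSet(
        {p: s for p, s in associations.items() if s}, term_names
    )
    truth = GroundTruth(assignment, module_arrays, planted)
    return matrix, metadata, annset, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
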