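"""Core in-memory containers shared by every analysis module.

The package works on feature x sample matrices (one per omic), a phenotype
table carrying one response variable plus optional confounders, gene-set
collections (GMT), and probe-to-gene mapping tables used to compress array
probes (e.g. 450K methylation probes) to gene-level values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "PhenotypeTable",
    "GeneSetCollection",
    "ProbeGeneMap",
    "probes_to_genes",
]


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = sorted(s[s.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class OmicsMatrix:
    """One omic's numeric values as features x samples.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_features, n_samples)``. Must be finite.
    feature_ids, sample_ids
        Unique identifiers matching the two axes.
    omic_label
        Free-text omic tag, e.g. ``"RNA"``, ``"DNAm"``, ``"miRNA"``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    omic_label: str = "omic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}; impute or drop before loading"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: list[str]) -> "OmicsMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in keep]
        return OmicsMatrix(self.values[idx], list(keep), list(self.sample_ids), self.omic_label)

    def subset_samples(self, keep: list[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return OmicsMatrix(self.values[:, idx], list(self.feature_ids), list(keep), self.omic_label)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype data: one response plus optional confounders.

    ``response`` is coerced to a two-level categorical when it has exactly two
    observed levels (reference = first level in sort order, so group effects
    have deterministic signs); otherwise it is treated as continuous.
    Confounders are typed independently: non-numeric columns, or numeric
    columns explicitly declared categorical, become categoricals.
    """

    data: pd.DataFrame
    response: str
    confounders: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.response not in self.data.columns:
            raise KeyError(f"response column {self.response!r} not found")
        for c in self.confounders:
            if c not in self.data.columns:
                raise KeyError(f"confounder column {c!r} not found")
        _check_unique(self.data.index, "sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def response_values(self) -> pd.Series:
        return self.data[self.response]

    def is_binary_response(self) -> bool:
        return self.data[self.response].nunique() == 2

    def binary_response_codes(self) -> tuple[np.ndarray, list]:
        """0/1 coding of a two-level response; levels sorted, first = reference."""
        vals = self.data[self.response]
        levels = sorted(vals.unique().tolist(), key=str)
        if len(levels) != 2:
            raise ValueError(
                f"response {self.response!r} has {len(levels)} level(s); exactly 2 required"
            )
        return (vals == levels[1]).to_numpy(dtype=float), levels

    def align_to(self, m: OmicsMatrix) -> "PhenotypeTable":
        """Reorder rows to the matrix's sample order.

        Every matrix sample must be present in the table; silent dropping of
        samples hides bugs, so partial coverage is a hard error.
        """
        missing = [s for s in m.sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"phenotype table lacks matrix samples: {missing}")
        return PhenotypeTable(self.data.loc[m.sample_ids].copy(), self.response, list(self.confounders))

    def confounder_design(self) -> np.ndarray:
        """Numeric confounder design (no intercept): categoricals dummy-coded."""
        cols = []
        for c in self.confounders:
            v = self.data[c]
            if v.dtype.kind in "biufc":
                cols.append(v.to_numpy(dtype=float)[:, None])
            else:
                if v.nunique() > 10:
                    raise ValueError(f"confounder {c!r} has >10 non-numeric levels")
                d = pd.get_dummies(v.astype("category"), drop_first=True)
                cols.append(d.to_numpy(dtype=float))
        if not cols:
            return np.empty((len(self.data), 0))
        return np.hstack(cols)


@dataclass
class GeneSetCollection:
    """Ordered collection of (term_id, term_name, member gene ids)."""

    terms: list[tuple[str, str, frozenset]]

    def __post_init__(self) -> None:
        for tid, _, members in self.terms:
            if len(members) < 1:
                raise ValueError(f"term {tid!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    def term_ids(self) -> list[str]:
        return [t[0] for t in self.terms]

    def gene_to_terms(self) -> dict[str, frozenset]:
        out: dict[str, set] = {}
        for tid, _, members in self.terms:
            for g in members:
                out.setdefault(g, set()).add(tid)
        return {g: frozenset(ts) for g, ts in out.items()}


@dataclass
class ProbeGeneMap:
    """Probe -> gene mapping; a probe may map to 0, 1 or many genes."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            seen, dups = set(), set()
            for p in self.pairs:
                (dups if p in seen else seen).add(p)
            raise ValueError(f"duplicate (probe, gene) pairs: {sorted(dups)}")

    def gene_to_probes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for probe, gene in self.pairs:
            out.setdefault(gene, []).append(probe)
        return out


def probes_to_genes(m: OmicsMatrix, pg_map: ProbeGeneMap, aggregator: str = "mean") -> OmicsMatrix:
    """Compress probe-level values to gene level.

    Each output gene row is the per-sample arithmetic mean over its mapped
    probes present in ``m``; probes mapping to k genes contribute to all k
    gene rows; unmapped probes are dropped.
    """
    if aggregator != "mean":
        raise ValueError(f"unsupported aggregator {aggregator!r}")
    probe_pos = {p: i for i, p in enumerate(m.feature_ids)}
    gene_rows: dict[str, list[int]] = {}
    for gene, probes in pg_map.gene_to_probes().items():
        idx = [probe_pos[p] for p in probes if p in probe_pos]
        if idx:
            gene_rows[gene] = idx
    if not gene_rows:
        raise ValueError("no probes in the map are present in the matrix")
    genes = sorted(gene_rows)
    values = np.vstack([m.values[gene_rows[g]].mean(axis=0) for g in genes])
    return OmicsMatrix(values, genes, list(m.sample_ids), m.omic_label)
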