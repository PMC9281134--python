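"""Synthetic data with full ground truth for every pipeline stage.

The generators emulate the data the pipeline consumes in a real two-species
comparison of fruit development:

* a reference gene set (cDNA models with optional second isoforms), standing
  in for a curated reference transcriptome,
* two diverged species transcript sets derived from it, with planted
  chimeric fusions (mis-assembly artifacts joining two genes) whose junction
  positions are recorded to the nucleotide,
* negative-binomial count matrices under the two-factor design
  species + structure + species:structure with planted main-effect (DEG)
  and interaction (DDEG) features,
* small-RNA read sets drawn from mature miRNA sequences with at most one
  substitution per read.

Mutations are substitutions only, so every planted coordinate stays exact.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ReferenceGeneSet",
    "TranscriptSet",
    "ChimeraTruth",
    "TruthTable",
    "CountExperiment",
    "generate_reference_gene_set",
    "generate_species_pair",
    "generate_count_experiment",
    "generate_mature_mirna_set",
    "generate_small_rna_reads",
    "SPECIES_LEVELS",
    "STRUCTURE_LEVELS",
]

SPECIES_LEVELS = ("A", "B")
STRUCTURE_LEVELS = ("bud", "flower", "fruit")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Invalid generator configuration (ranges, fractions, lengths)."""


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = np.zeros(arr.shape[0], dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[arr == b] = i
    hit = rng.random(arr.shape[0]) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        codes[hit] = (codes[hit] + shift) % 4
        arr = _BASES[codes]
    return bytes(arr).decode("ascii")


# ---------------------------------------------------------------------------
# reference gene set
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGeneSet:
    """Reference cDNA models: gene -> ordered isoform ids, id -> sequence."""

    genes: dict[str, list[str]]
    sequences: dict[str, str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def representative(self, gene_id: str) -> str:
        """First-listed isoform id of a gene (its representative model)."""
        return self.genes[gene_id][0]

    def representative_sequences(self) -> dict[str, str]:
        return {self.representative(g): self.sequences[self.representative(g)]
                for g in self.genes}


def generate_reference_gene_set(
    n_genes: int,
    isoform_fraction: float = 0.0,
    length_range: tuple[int, int] = (500, 2000),
    seed: int = 0,
) -> ReferenceGeneSet:
    """Random reference gene set; a fraction of genes carry a second isoform.

    Second isoforms are made by an internal deletion or an alternative 3'
    end removing 5-20% of the sequence, so isoforms of one gene share at
    least 80% of their sites.
    """
    if n_genes < 1:
        raise ConfigurationError(f"n_genes must be >= 1, got {n_genes}")
    lo, hi = length_range
    if not (200 <= lo <= hi <= 20000):
        raise ConfigurationError(
            f"length_range must lie within [200, 20000], got {length_range}"
        )
    if not 0.0 <= isoform_fraction <= 1.0:
        raise ConfigurationError("isoform_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes: dict[str, list[str]] = {}
    sequences: dict[str, str] = {}
    n_iso = int(round(isoform_fraction * n_genes))
    iso_genes = set(
        rng.choice(n_genes, size=n_iso, replace=False).tolist()
    )
    for i in range(n_genes):
        gid = f"G{i + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        genes[gid] = [f"{gid}.1"]
        sequences[f"{gid}.1"] = seq
        if i in iso_genes:
            frac = float(rng.uniform(0.05, 0.20))
            cut = max(1, int(round(frac * length)))
            if rng.random() < 0.5 and length - cut >= 200:
                start = int(rng.integers(50, length - cut - 50)) \
                    if length - cut > 100 else 0
                iso = seq[:start] + seq[start + cut:]
            else:
                iso = seq[: max(200, length - cut)]
            genes[gid].append(f"{gid}.2")
            sequences[f"{gid}.2"] = iso
    return ReferenceGeneSet(genes=genes, sequences=sequences)


# ---------------------------------------------------------------------------
# species pair with planted chimeras
# ---------------------------------------------------------------------------


@dataclass
class TranscriptSet:
    species: str
    sequences: dict[str, str]
    # transcript id -> source description ("G00001.1" or "chimera:G1+G2")
    origin: dict[str, str] = field(default_factory=dict)

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sequences.items()}


@dataclass(frozen=True)
class ChimeraTruth:
    transcript_id: str
    gene_5p: str
    gene_3p: str
    junction: int          # 1-based last position of 5'-gene-derived sequence
    kind: str              # "concat" (expected midpoint) or "interleaved"
    engineered_overlap: int


@dataclass
class TruthTable:
    chimera_truth: dict[str, list[ChimeraTruth]] = field(default_factory=dict)
    ortholog_truth: list[tuple[str, str, str]] = field(default_factory=list)
    effect_truth: pd.DataFrame | None = None


def generate_species_pair(
    ref: ReferenceGeneSet,
    divergence: float = 0.03,
    n_chimeras: int = 0,
    overlap_mix: float = 0.5,
    fragment_fraction: float = 0.0,
    seed: int = 0,
    interleave_len: int = 100,
) -> tuple[TranscriptSet, TranscriptSet, TruthTable]:
    """Two diverged transcript sets with planted chimeric fusions.

    Every reference isoform yields one independently mutated transcript per
    species (these are the true ortholog pairs).  Per species, ``n_chimeras``
    extra transcripts fuse mutated copies of two distinct genes:
    ``overlap_mix`` of them are plain concatenations whose two reference
    hits abut on the fusion (overlap ~0 nt, the midpoint-split branch);
    the rest interleave ``interleave_len`` nt of each gene around the
    junction so the merged reference hits overlap by ~2x that length
    (the corrected-boundary branch).  ``fragment_fraction`` of the ordinary
    transcripts are truncated to 55-80% of their length.
    """
    if not 0.0 <= divergence <= 0.1:
        raise ConfigurationError(
            f"divergence must be in [0, 0.1], got {divergence}"
        )
    if n_chimeras > len(ref.genes) // 2:
        raise ConfigurationError("n_chimeras must be <= n_genes / 2")
    if not 0.0 <= overlap_mix <= 1.0 or not 0.0 <= fragment_fraction <= 1.0:
        raise ConfigurationError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    iso_ids = list(ref.sequences)
    sets: list[TranscriptSet] = []
    per_species_ids: dict[str, list[str]] = {}
    for species in SPECIES_LEVELS:
        tset = TranscriptSet(species=species, sequences={}, origin={})
        ids_for_iso: list[str] = []
        for i, iso in enumerate(iso_ids):
            tid = f"{species}_T{i + 1:05d}"
            tset.sequences[tid] = _mutate(ref.sequences[iso], divergence, rng)
            tset.origin[tid] = iso
            ids_for_iso.append(tid)
        # fragments: truncate a fraction of ordinary transcripts
        n_frag = int(round(fragment_fraction * len(ids_for_iso)))
        frag_idx = rng.choice(len(ids_for_iso), size=n_frag, replace=False)
        for fi in sorted(frag_idx.tolist()):
            tid = ids_for_iso[fi]
            seq = tset.sequences[tid]
            keep = max(250, int(round(len(seq) * rng.uniform(0.55, 0.80))))
            if keep >= len(seq):
                continue
            if rng.random() < 0.5:
                tset.sequences[tid] = seq[:keep]
            else:
                tset.sequences[tid] = seq[len(seq) - keep:]
        # chimeras
        gene_ids = ref.gene_ids
        chosen = rng.choice(len(gene_ids), size=2 * n_chimeras, replace=False)
        n_concat = int(round(overlap_mix * n_chimeras))
        calls: list[ChimeraTruth] = []
        for c in range(n_chimeras):
            gx = gene_ids[int(chosen[2 * c])]
            gy = gene_ids[int(chosen[2 * c + 1])]
            mut_x = _mutate(ref.sequences[ref.representative(gx)],
                            divergence, rng)
            mut_y = _mutate(ref.sequences[ref.representative(gy)],
                            divergence, rng)
            tid = f"{species}_C{c + 1:03d}"
            if c < n_concat:
                seq = mut_x + mut_y
                calls.append(ChimeraTruth(tid, gx, gy, len(mut_x),
                                          "concat", 0))
            else:
                v = min(interleave_len, len(mut_x) // 3, len(mut_y) // 3)
                seq = (mut_x[: len(mut_x) - v] + mut_y[:v]
                       + mut_x[len(mut_x) - v:] + mut_y[v:])
                calls.append(ChimeraTruth(tid, gx, gy, len(mut_x) + v,
                                          "interleaved", 2 * v))
            tset.sequences[tid] = seq
            tset.origin[tid] = f"chimera:{gx}+{gy}"
        truth.chimera_truth[species] = calls
        per_species_ids[species] = ids_for_iso
        sets.append(tset)
    for i, iso in enumerate(iso_ids):
        truth.ortholog_truth.append(
            (per_species_ids["A"][i], per_species_ids["B"][i],
             iso.rsplit(".", 1)[0])
        )
    return sets[0], sets[1], truth


# ---------------------------------------------------------------------------
# count experiment
# ---------------------------------------------------------------------------


@dataclass
class CountExperiment:
    """Features x samples counts with metadata, lengths and feature kind."""

    counts: pd.DataFrame                 # integer, features x samples
    sample_meta: pd.DataFrame            # index = samples; species, structure, replicate
    feature_lengths: pd.Series | None    # nt per feature (None for miRNAs)
    feature_kind: str = "transcript"     # "transcript" or "mirna"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("transcript", "mirna"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("counts columns must match sample_meta index")
        if self.feature_kind == "transcript":
            if self.feature_lengths is None:
                raise ValueError("transcript experiments need feature_lengths")
            if not self.counts.index.equals(self.feature_lengths.index):
                raise ValueError("feature_lengths index must match counts")

    def subset(self, features) -> "CountExperiment":
        lengths = (None if self.feature_lengths is None
                   else self.feature_lengths.loc[features])
        return CountExperiment(self.counts.loc[features], self.sample_meta,
                               lengths, self.feature_kind)


def make_sample_meta(n_reps: int = 3) -> pd.DataFrame:
    rows = []
    for sp in SPECIES_LEVELS:
        for st in STRUCTURE_LEVELS:
            for r in range(1, n_reps + 1):
                rows.append((f"{sp}_{st}_{r}", sp, st, r))
    meta = pd.DataFrame(rows, columns=["sample", "species", "structure",
                                       "replicate"]).set_index("sample")
    return meta


def generate_count_experiment(
    features: int = 2000,
    n_reps: int = 3,
    baseline_mean_log2: tuple[float, float] = (5.0, 11.0),
    dispersion: float = 0.1,
    deg_fraction: float = 0.0,
    ddeg_fraction: float = 0.0,
    effect_size_log2: float = 2.0,
    seed: int = 0,
    feature_lengths: pd.Series | None = None,
    feature_kind: str = "transcript",
) -> tuple[CountExperiment, TruthTable]:
    """NB counts under species + structure + species:structure.

    Baseline reference-cell (species A, bud) mean counts are 2^U with U
    uniform over ``baseline_mean_log2``.  ``ddeg_fraction`` of features get
    nonzero interaction coefficients (both structure transitions) of
    magnitude ``effect_size_log2`` with random signs; a disjoint
    ``deg_fraction`` get main-effect shifts only (species or structure,
    chosen at random per feature).  Counts are NB with variance
    mu + dispersion * mu^2; ``dispersion == 0`` gives Poisson counts.
    Transcript means scale with length (per-kilobase expression is what the
    baseline refers to after dividing out length).
    """
    if not 0.0 <= deg_fraction <= 1.0 or not 0.0 <= ddeg_fraction <= 1.0:
        raise ConfigurationError("fractions must be in [0, 1]")
    if deg_fraction + ddeg_fraction > 1.0:
        raise ConfigurationError("deg_fraction + ddeg_fraction must be <= 1")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    meta = make_sample_meta(n_reps)
    fids = [f"F{i + 1:05d}" for i in range(features)]
    if feature_kind == "transcript":
        if feature_lengths is None:
            lengths = pd.Series(
                rng.integers(400, 3001, size=features), index=fids,
                name="length",
            )
        else:
            if len(feature_lengths) != features:
                raise ConfigurationError(
                    "feature_lengths must have one entry per feature"
                )
            lengths = feature_lengths.copy()
            fids = [str(i) for i in lengths.index]
            lengths.index = pd.Index(fids)
        log_len_kb = np.log(lengths.to_numpy(dtype=float) / 1000.0)
    else:
        lengths = None
        log_len_kb = np.zeros(features)

    ln2 = np.log(2.0)
    n_ddeg = int(round(ddeg_fraction * features))
    n_deg = int(round(deg_fraction * features))
    perm = rng.permutation(features)
    ddeg_idx = np.sort(perm[:n_ddeg])
    deg_idx = np.sort(perm[n_ddeg:n_ddeg + n_deg])

    beta_log2 = np.zeros((features, 6))  # intercept, B, flower, fruit, B:flower, B:fruit
    base = rng.uniform(baseline_mean_log2[0], baseline_mean_log2[1],
                       size=features)
    beta_log2[:, 0] = base
    signs = lambda n: rng.choice([-1.0, 1.0], size=n)  # noqa: E731
    beta_log2[ddeg_idx, 4] = signs(n_ddeg) * effect_size_log2
    beta_log2[ddeg_idx, 5] = signs(n_ddeg) * effect_size_log2
    deg_type = rng.random(n_deg) < 0.5
    sp_idx = deg_idx[deg_type]
    st_idx = deg_idx[~deg_type]
    beta_log2[sp_idx, 1] = signs(len(sp_idx)) * effect_size_log2
    beta_log2[st_idx, 2] = signs(len(st_idx)) * effect_size_log2
    beta_log2[st_idx, 3] = signs(len(st_idx)) * effect_size_log2

    from .design import build_design_matrices  # local import, no cycle
    X_full, _ = build_design_matrices(meta)
    X = X_full.to_numpy(dtype=float)  # samples x 6
    log_mu = (beta_log2 * ln2) @ X.T + log_len_kb[:, None]
    mu = np.exp(log_mu)
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=fids, columns=meta.index,
                             dtype=np.int64)
    if lengths is not None:
        lengths.index = counts_df.index

    truth = TruthTable()
    eff = pd.DataFrame(
        beta_log2,
        index=counts_df.index,
        columns=["baseline_log2", "beta_species", "beta_flower",
                 "beta_fruit", "beta_int_flower", "beta_int_fruit"],
    )
    eff["is_ddeg"] = False
    eff.iloc[ddeg_idx, eff.columns.get_loc("is_ddeg")] = True
    eff["is_deg"] = False
    eff.iloc[deg_idx, eff.columns.get_loc("is_deg")] = True
    eff["dispersion"] = dispersion
    truth.effect_truth = eff
    exp = CountExperiment(counts=counts_df, sample_meta=meta,
                          feature_lengths=lengths, feature_kind=feature_kind)
    return exp, truth


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------


def generate_mature_mirna_set(
    n_families: int = 20,
    variant_fraction: float = 0.3,
    length_range: tuple[int, int] = (20, 22),
    seed: int = 0,
) -> dict[str, str]:
    """Mature miRNA reference: random matures; a fraction of families get a
    second member at Hamming distance 1 (exercising the collapsing rule)."""
    if not (18 <= length_range[0] <= length_range[1] <= 26):
        raise ConfigurationError("mature lengths must lie within 18-26 nt")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    n_var = int(round(variant_fraction * n_families))
    var_set = set(rng.choice(n_families, size=n_var, replace=False).tolist())
    for i in range(n_families):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_seq(rng, length)
        out[f"miR{i + 1:03d}a"] = seq
        if i in var_set:
            pos = int(rng.integers(0, length))
            old = "ACGT".index(seq[pos])
            new = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
            out[f"miR{i + 1:03d}b"] = seq[:pos] + new + seq[pos + 1:]
    return out


def generate_small_rna_reads(
    mirna_ref: Mapping[str, str],
    abundance: pd.DataFrame,
    mismatch_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Small-RNA reads per sample drawn from mature miRNA sequences.

    ``abundance`` is a matures x samples table of Poisson mean read counts.
    Each read equals its source mature with probability ``1 - mismatch_rate``
    and carries exactly one substitution otherwise.  Returns the reads per
    sample and the realized source-read counts (the planted truth).
    """
    if not 0.0 <= mismatch_rate <= 1.0:
        raise ConfigurationError("mismatch_rate must be in [0, 1]")
    for name, seq in mirna_ref.items():
        if not 18 <= len(seq) <= 26:
            raise ConfigurationError(
                f"mature sequence {name!r} has length {len(seq)}, "
                "outside 18-26 nt"
            )
        if set(seq.upper()) - set("ACGUT"):
            raise ConfigurationError(f"mature {name!r} has non-ACGU symbols")
    missing = set(abundance.index) - set(mirna_ref)
    if missing:
        raise ConfigurationError(f"abundance rows not in reference: {missing}")
    rng = np.random.default_rng(seed)
    reads: dict[str, list[str]] = {s: [] for s in abundance.columns}
    realized = pd.DataFrame(0, index=abundance.index,
                            columns=abundance.columns, dtype=np.int64)
    for sample in abundance.columns:
        for name in abundance.index:
            seq = mirna_ref[name].upper().replace("U", "T")
            n = int(rng.poisson(float(abundance.at[name, sample])))
            realized.at[name, sample] = n
            for _ in range(n):
                if mismatch_rate > 0 and rng.random() < mismatch_rate:
                    pos = int(rng.integers(0, len(seq)))
                    old = "ACGT".index(seq[pos])
                    new = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
                    reads[sample].append(seq[:pos] + new + seq[pos + 1:])
                else:
                    reads[sample].append(seq)
    return reads, realized
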