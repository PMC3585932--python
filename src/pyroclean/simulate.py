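"""Synthetic template communities and 454-like reads with a truth table.

The generator emulates the structure of a pyrosequencing experiment on a
mock community: a set of indel-free template haplotypes of known pairwise
divergence, sequenced with homopolymer-biased indel errors and uniform point
errors, with low-abundance numts (nuclear pseudogene copies) attached to
their parent templates.  Every read's template of origin is recorded, so
every pipeline stage can be checked against ground truth.

Templates follow a star layout: a centre sequence plus ``n - 1`` haplotypes
carrying alternate alleles at subsets of ``max_div`` designated variable
columns (two states per column, like third codon positions).  Pairwise
Hamming distance is then the symmetric difference of the allele sets, which
keeps every pair within ``[min_div, max_div]`` while an inclusive consensus
of the templates stays unambiguous outside the variable columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .read_prep import Read

__all__ = ["ErrorModel", "TruthTable", "simulate_templates", "simulate_reads"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ErrorModel:
    """Error process applied to each simulated read.

    ``hp_indel_rate`` is the per-homopolymer-run indel probability for a
    two-base run; longer runs are noisier, scaling linearly with
    ``run_length - 1`` (so a 4-base run is three times as error-prone as a
    2-base run).  Accepted indels are insertions or deletions with equal
    probability.  ``point_error_rate`` is the per-base substitution
    probability.  Numts are emitted as extra low-abundance templates:
    ``numt_per_template`` copies per template, each ``numt_divergence``
    mismatches from its parent, sequenced at ``numt_rel_abundance`` times
    the parent's abundance.
    """

    hp_indel_rate: float = 0.005
    point_error_rate: float = 0.001
    numt_per_template: int = 2
    numt_divergence: tuple[int, int] = (1, 2)
    numt_rel_abundance: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.hp_indel_rate, self.point_error_rate, self.numt_rel_abundance):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must lie in [0, 1]")
        if self.numt_per_template < 0:
            raise ValueError("numt_per_template must be >= 0")


@dataclass
class TruthTable:
    """Ground truth for one simulation."""

    #: template name -> sequence (includes numts)
    sequences: dict[str, str]
    #: template name -> sampling abundance (sums to 1 over templates + numts)
    abundances: dict[str, float]
    #: numt name -> parent template name
    numt_parents: dict[str, str]
    #: read id -> source template/numt name
    read_sources: dict[str, str] = field(default_factory=dict)

    @property
    def template_names(self) -> list[str]:
        return [n for n in self.sequences if n not in self.numt_parents]

    @property
    def numt_names(self) -> list[str]:
        return list(self.numt_parents)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_templates(
    n: int = 27,
    length: int = 220,
    min_div: int = 1,
    max_div: int = 60,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Generate ``n`` indel-free templates with pairwise Hamming distances in
    ``[min_div, max_div]``.  Deterministic per seed.
    """
    if n < 2:
        raise ValueError("need at least two templates")
    if not 1 <= min_div <= max_div <= length:
        raise ValueError("require 1 <= min_div <= max_div <= length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(200):
        centre = _random_seq(rng, length)
        n_var = max_div
        var_cols = rng.choice(length, size=n_var, replace=False)
        alt = np.array(
            [rng.choice([b for b in "ACGT" if b != centre[c]]) for c in var_cols]
        )
        seqs = [centre.copy()]
        for _ in range(n - 1):
            size = int(rng.integers(min_div, max_div + 1))
            pick = rng.choice(n_var, size=min(size, n_var), replace=False)
            s = centre.copy()
            s[var_cols[pick]] = alt[pick]
            seqs.append(s)
        arr = np.array(seqs)
        dist = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        iu = np.triu_indices(n, k=1)
        pair = dist[iu]
        if pair.min() >= min_div and pair.max() <= max_div:
            return {
                f"template_{k + 1:02d}": "".join(s) for k, s in enumerate(seqs)
            }
    raise RuntimeError(
        "could not place templates within the requested divergence window"
    )


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of >= 2 identical adjacent bases, as (start, end_excl)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j))
        i = j
    return runs


def _mutate_read(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    chars = list(seq)
    # homopolymer indels, applied 3'->5' so indices stay valid
    for start, end in reversed(_homopolymer_runs(seq)):
        p = min(1.0, model.hp_indel_rate * (end - start - 1))
        if rng.random() < p:
            if rng.random() < 0.5:
                chars.insert(start, seq[start])
            else:
                del chars[start]
    # uniform point errors
    out = []
    for ch in chars:
        if rng.random() < model.point_error_rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        else:
            out.append(ch)
    return "".join(out)


def _make_numt(
    parent: str,
    divergence: tuple[int, int],
    taken: set[str],
    rng: np.random.Generator,
) -> str:
    for _ in range(100):
        d = int(rng.integers(divergence[0], divergence[1] + 1))
        pos = rng.choice(len(parent), size=d, replace=False)
        chars = list(parent)
        for pidx in pos:
            chars[pidx] = str(rng.choice([b for b in "ACGT" if b != chars[pidx]]))
        numt = "".join(chars)
        if numt not in taken:
            return numt
    raise RuntimeError("could not generate a distinct numt sequence")


def simulate_reads(
    templates: dict[str, str],
    abundances: dict[str, float] | None = None,
    n_reads: int = 10_000,
    error_model: ErrorModel | None = None,
    seed: int | np.random.Generator = 0,
    primer: str | None = None,
) -> tuple[list[Read], TruthTable]:
    """Draw reads from templates (plus injected numts) and mutate them.

    Each read picks a source by abundance (uniform over templates by
    default; numts at ``numt_rel_abundance`` of their parent), then passes
    through the homopolymer-indel and point-error processes.  When
    ``primer`` is given, one concrete realisation of the (possibly
    degenerate) primer is prepended to every read, as in raw demultiplexed
    454 data.  Returns the reads and the truth table.
    """
    model = error_model or ErrorModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if abundances is None:
        abundances = {name: 1.0 / len(templates) for name in templates}
    if set(abundances) != set(templates):
        raise ValueError("abundances must cover exactly the template names")

    sequences = dict(templates)
    weights = dict(abundances)
    numt_parents: dict[str, str] = {}
    taken = set(templates.values())
    for name in list(templates):
        for k in range(model.numt_per_template):
            numt_name = f"{name}_numt{k + 1}"
            numt = _make_numt(templates[name], model.numt_divergence, taken, rng)
            taken.add(numt)
            sequences[numt_name] = numt
            weights[numt_name] = abundances[name] * model.numt_rel_abundance
            numt_parents[numt_name] = name

    total_w = sum(weights.values())
    names = list(weights)
    probs = np.array([weights[n] / total_w for n in names])
    truth = TruthTable(
        sequences=sequences,
        abundances={n: weights[n] / total_w for n in names},
        numt_parents=numt_parents,
    )

    if primer is not None:
        from .iupac import IUPAC_TO_BASES

        primer_real = "".join(
            str(rng.choice(sorted(IUPAC_TO_BASES[ch.upper()]))) for ch in primer
        )
    else:
        primer_real = ""

    sources = rng.choice(len(names), size=n_reads, p=probs)
    reads = []
    width = len(str(n_reads))
    for k, src_idx in enumerate(sources):
        src = names[int(src_idx)]
        seq = _mutate_read(sequences[src], model, rng)
        rid = f"read_{k:0{width}d}"
        reads.append(Read(rid, primer_real + seq))
        truth.read_sources[rid] = src
    return reads, truth
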