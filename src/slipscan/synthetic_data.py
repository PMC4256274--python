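"""Designed slippery-site genes and stochastic slippage simulation.

The generator builds genes with the architecture of the natural locus: an
upstream coding region, a poly-A run, a short spacer, a premature in-frame
amber stop, and a downstream open reading frame readable in the +1 frame.
The default geometry mirrors the Citrobacter rodentium tssM1 gene: 794
upstream codons, an 11-A run, a 28-nt spacer (truncated product 807 aa, ORF
2,424 nt including the stop) and 320 restored-frame codons past the stop
(full-length product 1,129 aa).

Transcription is simulated as one net slippage edit k drawn per transcript
(not per polymerase step) — a deliberate simplification sufficient to
reproduce the observed 10-15 A mRNA species around a native 11-A run while
keeping the model identifiable. Western and reporter readouts add
multiplicative lognormal and additive Gaussian noise respectively. All
simulations are reproducible: a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, InputError
from .frequency_quant import BandQuant, ReporterSet
from .seq_core import Cds, STOP_CODONS, translate
from .slippage_scan import (
    HomopolymerRun,
    ScanConfig,
    call_slippery_sites,
    find_premature_stop,
    find_runs,
    is_restoring_edit,
)
from .variant_predict import apply_slippage_edit

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class GeneDesign:
    """Parameters of a designed slippery-site gene.

    ``upstream_codons`` counts codons before the run including the start
    codon; ``spacer_nt`` is the distance between the last run base and the
    premature stop; ``plus1_orf_codons`` counts full restored-frame codons
    strictly downstream of the premature stop codon (0 designs a gene whose
    +1 frame terminates before passing the stop). run_length + spacer_nt must
    be a multiple of 3 so the designed stop is in frame.
    """

    upstream_codons: int = 794
    run_length: int = 11
    spacer_nt: int = 28
    plus1_orf_codons: int = 320
    seed: int = 0
    gene_id: str = "synthetic_slip_gene"

    def __post_init__(self) -> None:
        if self.upstream_codons < 2:
            raise InputError("upstream_codons must be >= 2")
        if self.run_length < 4:
            raise InputError("run_length must be >= 4")
        if self.spacer_nt < 3:
            raise InputError("spacer_nt must be >= 3")
        if self.plus1_orf_codons < 0:
            raise InputError("plus1_orf_codons must be >= 0")
        if (self.run_length + self.spacer_nt) % 3 != 0:
            raise InputError(
                "run_length + spacer_nt must be a multiple of 3 so the premature "
                f"stop is in frame (got {self.run_length} + {self.spacer_nt})"
            )


@dataclass(frozen=True)
class SlippageModel:
    """Per-transcript net-edit distribution p(k); defaults to p(+1)=0.25 with
    the remainder on k=0, matching the estimated natural slippage frequency."""

    probabilities: dict = field(default_factory=lambda: {0: 0.75, 1: 0.25})
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.probabilities
        if not p:
            raise InputError("empty slippage distribution")
        if any(v < 0 for v in p.values()):
            raise InputError("slippage probabilities must be non-negative")
        total = sum(p.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"slippage probabilities must sum to 1, got {total}")


@dataclass(frozen=True)
class SimulatedPopulation:
    """Counts from one simulated transcript population."""

    n_transcripts: int
    native_a_count: int
    k_counts: dict
    a_count_counts: dict
    variant_counts: dict  # protein length (aa) -> transcript count
    variant_by_k: dict  # k -> protein length (aa)
    restored_by_k: dict  # k -> bool
    true_restoring_fraction: float


def _has_long_homorun(s: str, min_run: int) -> bool:
    for base in "AT":
        count = 0
        for ch in s:
            count = count + 1 if ch == base else 0
            if count >= min_run:
                return True
    return False


def _sample_codons(rng, n, min_run, prefix_tail=""):
    """n random sense codons, rejecting any that create an A/T run >= min_run."""
    parts = []
    tail = prefix_tail
    for _ in range(n):
        for _ in range(200):
            codon = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
            if not _has_long_homorun(tail + codon, min_run):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise GenerationError("could not sample a codon without a long homorun")
        parts.append(codon)
        tail = (tail + codon)[-(min_run + 2) :]
    return "".join(parts)


def _verify(gene: Cds, d: GeneDesign, min_run: int) -> bool:
    u = 3 * d.upstream_codons
    stop_start = u + d.run_length + d.spacer_nt + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if find_premature_stop(gene) != stop_start:
            return False
    a_runs = find_runs(gene, "A", min_run)
    t_runs = find_runs(gene, "T", min_run)
    if t_runs or len(a_runs) != 1:
        return False
    run = a_runs[0]
    if run.start != u + 1 or run.length != d.run_length:
        return False
    sites = call_slippery_sites(gene, ScanConfig(min_run_length=min_run))
    if len(sites) != 1 or sites[0].distance != d.spacer_nt:
        return False
    plus1_restores = 1 in sites[0].restoring_edits
    return plus1_restores == (d.plus1_orf_codons > 0)


def design_gene(d: GeneDesign, min_scan_run: int = 8, max_attempts: int = 200) -> Cds:
    """Generate a gene satisfying every design invariant, deterministically
    under the design's seed.

    The gene contains no unintended in-frame stop before the designed one, no
    unintended A/T run of scannable length, and a restored-frame stop only at
    the designed terminus. Construction is by rejection sampling with a final
    verification through the scanner itself.
    """
    rng = np.random.default_rng(d.seed)
    u = 3 * d.upstream_codons

    # upstream: fixed start codon, then sense codons; last base must differ
    # from A so the designed run is maximal
    for _ in range(50):
        upstream = "ATG" + _sample_codons(rng, d.upstream_codons - 1, min_scan_run, "ATG")
        if upstream[-1] != "A":
            break
    else:
        raise GenerationError("could not end the upstream region off-base")

    run_seq = "A" * d.run_length
    for _ in range(max_attempts):
        # spacer: random, first base off the run base, with the designed
        # restored-frame stop planted when no downstream ORF is wanted
        spacer = list("".join(rng.choice(list("ACGT"), size=d.spacer_nt)))
        if spacer[0] == "A":
            spacer[0] = rng.choice(list("CGT"))
        if d.plus1_orf_codons == 0:
            b = (-(u + d.run_length + 1)) % 3
            if b + 3 > d.spacer_nt:
                raise GenerationError("spacer too short to host the +1-frame terminus")
            # planted terminus starts with T, so it never extends the A run
            spacer[b : b + 3] = "TAA"
        spacer = "".join(spacer)

        if d.plus1_orf_codons > 0:
            completion = (-(u + d.run_length + 1 + d.spacer_nt)) % 3
            downstream = (
                "".join(rng.choice(list("ACGT"), size=completion))
                + _sample_codons(rng, d.plus1_orf_codons, min_scan_run)
                + "TAA"
            )
        else:
            # keep the designed stop premature: a short frame-0 tail follows it
            downstream = _sample_codons(rng, 5, min_scan_run) + "TAA"

        gene = Cds(
            id=d.gene_id,
            seq=upstream + run_seq + spacer + "TAG" + downstream,
            alphabet="DNA",
            source="synthetic",
        )
        if _verify(gene, d, min_scan_run):
            return gene
    raise GenerationError(
        f"design infeasible after {max_attempts} attempts (seed {d.seed}): {d}"
    )


def designed_run(d: GeneDesign) -> HomopolymerRun:
    """The designed gene's poly-A run (coordinates fixed by the design)."""
    return HomopolymerRun(
        seq_id=d.gene_id, base="A", start=3 * d.upstream_codons + 1, length=d.run_length
    )


def simulate_transcription(
    cds: Cds,
    run: HomopolymerRun,
    model: SlippageModel,
    n: int,
    seed: int | None = None,
) -> SimulatedPopulation:
    """Draw one net slippage edit per transcript and tally mRNA/protein species.

    ``true_restoring_fraction`` is the model-true probability mass on
    frame-restoring edits, independent of the sampled counts.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    support = sorted(model.probabilities)
    probs = np.array([model.probabilities[k] for k in support], dtype=float)
    probs = probs / probs.sum()
    ks = rng.choice(support, size=n, p=probs)
    k_counts = Counter(int(k) for k in ks)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stop = find_premature_stop(cds)
    variant_by_k, restored_by_k = {}, {}
    for k in support:
        edit = apply_slippage_edit(cds, run, k)
        edited = Cds(id=f"{cds.id}|k={k:+d}", seq=edit.edited_seq, alphabet=cds.alphabet,
                     source="edited")
        variant_by_k[k] = len(translate(edited))
        restored_by_k[k] = False if stop is None else is_restoring_edit(cds, run, k, stop)

    a_count_counts = Counter()
    variant_counts = Counter()
    for k, c in k_counts.items():
        a_count_counts[run.length + k] += c
        variant_counts[variant_by_k[k]] += c
    true_restoring = float(
        sum(model.probabilities[k] for k in support if restored_by_k[k])
    )
    return SimulatedPopulation(
        n_transcripts=n,
        native_a_count=run.length,
        k_counts=dict(k_counts),
        a_count_counts=dict(a_count_counts),
        variant_counts=dict(variant_counts),
        variant_by_k=variant_by_k,
        restored_by_k=restored_by_k,
        true_restoring_fraction=true_restoring,
    )


def simulate_western(
    pop: SimulatedPopulation, noise_sigma: float = 0.05, seed: int = 0
) -> BandQuant:
    """Band intensities for the two dominant variants, proportional to
    transcript counts times multiplicative lognormal noise exp(N(0, sigma^2))."""
    if len(pop.variant_counts) < 2:
        raise InputError("western simulation needs two dominant protein variants")
    rng = np.random.default_rng(seed)
    top2 = sorted(pop.variant_counts, key=pop.variant_counts.get, reverse=True)[:2]
    long_len, short_len = max(top2), min(top2)
    noise_long, noise_short = np.exp(rng.normal(0.0, noise_sigma, size=2))
    native_len = pop.variant_by_k.get(0)
    slippage_product = "long" if native_len != long_len else "short"
    return BandQuant(
        lane_id=f"sim_seed{seed}",
        intensity_long=pop.variant_counts[long_len] * noise_long,
        intensity_short=pop.variant_counts[short_len] * noise_short,
        slippage_product=slippage_product,
    )


def simulate_reporters(
    true_f: float,
    f_max_scale: float = 1000.0,
    noise_sigma: float = 10.0,
    replicates: int = 3,
    seed: int = 0,
    background: float = 50.0,
) -> ReporterSet:
    """Three-construct reporter readouts for a true slippage frequency.

    f_neg sits at background, f_max at background + span, f_test at the
    ``true_f`` fraction of the span; Gaussian noise (A.U.) is added per
    replicate. Background and span defaults are arbitrary units chosen for a
    realistic signal-to-background, not quantitative claims.
    """
    if not 0.0 <= true_f <= 1.0:
        raise InputError("true_f must be in [0, 1]")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    span = f_max_scale
    neg = background + rng.normal(0.0, noise_sigma, size=replicates)
    test = background + true_f * span + rng.normal(0.0, noise_sigma, size=replicates)
    mx = background + span + rng.normal(0.0, noise_sigma, size=replicates)
    return ReporterSet(
        f_neg=float(np.mean(neg)),
        f_test=float(np.mean(test)),
        f_max=float(np.mean(mx)),
        replicates=replicates,
        per_replicate={"f_neg": neg.tolist(), "f_test": test.tolist(), "f_max": mx.tolist()},
    )
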