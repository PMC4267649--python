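"""End-to-end motif prediction: enumerate, thread, score, build the PWM."""

from __future__ import annotations

from .baseswap import enumerate_kmers, relax_clashes, swap_bases
from .motifgen import (AffinityParams, AffinityTable, PWM, add_affinities,
                       build_pwm, normalize_scores, select_sites)
from .potential import (DistanceBinning, PairPotential, ScoreTable,
                        score_interface)
from .structio import CuratedComplex


def thread_and_score(c: CuratedComplex, pot: PairPotential,
                     binning: DistanceBinning | None = None,
                     relax: bool = False, relax_steps: int = 100
                     ) -> ScoreTable:
    """Score every 4^k threaded model of the curated complex."""
    binning = binning or pot.binning
    scores: dict[str, float] = {}
    for kmer in enumerate_kmers(c.k):
        model = swap_bases(c, kmer)
        if relax:
            model = relax_clashes(model, steps=relax_steps)
        scores[kmer] = score_interface(model, pot, binning)
    return ScoreTable(scores)


def predict_motif(c: CuratedComplex, pot: PairPotential,
                  params: AffinityParams | None = None,
                  binning: DistanceBinning | None = None,
                  relax: bool = False, relax_steps: int = 100,
                  name: str | None = None
                  ) -> tuple[PWM, AffinityTable]:
    """Full prediction for one curated complex.

    Returns the affinity-weighted PWM together with the complete affinity
    table (raw score, normalized score and relative affinity per k-mer).
    """
    params = params or AffinityParams()
    table = normalize_scores(
        thread_and_score(c, pot, binning, relax, relax_steps))
    add_affinities(table, params)
    sites = select_sites(table, params)
    pwm = build_pwm(sites, name=name if name is not None else c.identifier)
    return pwm, table
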