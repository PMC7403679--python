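"""In-memory convenience workflows composing the simulator and the scans.

These avoid the file round-trips of :func:`nichescan.pipeline.run_pipeline`
for replicated analyses (power studies, calibration runs) where only the
final statistics are needed.
"""

from __future__ import annotations

from .branch import PbsTrack, pbs_scan
from .config import SimConfig
from .popgen import AlleleCounts, allele_counts, make_windows, window_fst
from .simulate import simulate_frequencies, simulate_genotypes

__all__ = ["simulate_counts", "divergence_scan"]


def simulate_counts(sim: SimConfig, branches: tuple[str, str, str]) -> AlleleCounts:
    """Simulate genotypes under *sim* and tally allele counts per branch."""
    freqs = simulate_frequencies(sim)
    gm = simulate_genotypes(freqs, sim)
    return allele_counts(gm, list(branches))


def divergence_scan(sim: SimConfig, branches: tuple[str, str, str],
                    window_size: int = 2000, step: int | None = None,
                    estimator: str = "hudson",
                    counts: AlleleCounts | None = None) -> PbsTrack:
    """Simulate (unless ``counts`` is given) and run a windowed PBS scan.

    ``branches`` orders the tree as (focal1, focal2, outgroup); the returned
    track carries per-window PBS for all three.
    """
    if counts is None:
        counts = simulate_counts(sim, branches)
    b1, b2, b3 = branches
    windows = make_windows(sim.contig_lengths, window_size, step)
    return pbs_scan(
        window_fst(counts, b1, b2, windows, estimator),
        window_fst(counts, b1, b3, windows, estimator),
        window_fst(counts, b2, b3, windows, estimator),
    )
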