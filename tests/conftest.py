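"""Shared fixtures: small genomes, clone sets, and a default pipeline run."""

from __future__ import annotations

import pytest

from bacmap.simulate import (
    SimParams,
    make_reference,
    sample_clones,
)


@pytest.fixture(scope="session")
def sim_params() -> SimParams:
    return SimParams(seed=11)


@pytest.fixture(scope="session")
def small_genome():
    """One 2.25 Mb chromosome: the smallest scale that hosts clones."""
    return make_reference(1, 2_250_000, 0.35, seed=42)


@pytest.fixture(scope="session")
def small_clones(small_genome, sim_params):
    return sample_clones(small_genome, "LIB_T", "HindIII", 40, sim_params, seed=5)


@pytest.fixture(scope="session")
def pipeline_bundle():
    """One default-configuration pipeline run, shared across tests."""
    from bacmap.report import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=20240801 % 2**31))


def synthetic_marker_hits():
    """Synthetic marker-hit set reproducing published-scale marginal tallies.

    Builds 3952 SSR and 676 RFLP markers whose contig-count bins
    (0/1/2/>2 contigs) and clone-count bins (1/2-4/5-9/>=10 clones) match a
    real soybean-map marker screen, together with a synthetic
    clone-to-contig mapping. The multiple-hit-marker class totals implied by
    those marginals are 41 multi-singleton, 503 single-contig-multi-clone
    and 1181 multi-contig markers.
    """
    from bacmap.markers import MarkerHit

    # (marker_type, n_markers, n_contigs per marker, n_clones per marker)
    # chosen so the contig bins (SSR 417/2601/301/633, RFLP 98/331/145/102),
    # clone bins (SSR 2698/451/631/172, RFLP 205/306/125/40) and MHM class
    # totals (41 / 503 / 1181) all come out exactly
    specs: list[tuple[str, int, int, int]] = [
        ("SSR", 2311, 1, 1),
        ("SSR", 387, 0, 1),
        ("SSR", 30, 0, 2),    # multi-singleton MHM
        ("SSR", 290, 1, 2),   # single-contig multi-clone MHM
        ("SSR", 131, 2, 2),   # multi-contig MHM, 2-4 clone bin
        ("SSR", 170, 2, 5),   # multi-contig, 5-9 clone bin
        ("SSR", 461, 3, 5),
        ("SSR", 172, 3, 10),  # multi-contig, >=10 clone bin
        ("RFLP", 118, 1, 1),
        ("RFLP", 87, 0, 1),
        ("RFLP", 11, 0, 2),   # multi-singleton
        ("RFLP", 213, 1, 2),  # single-contig multi-clone
        ("RFLP", 82, 2, 2),
        ("RFLP", 63, 2, 5),
        ("RFLP", 62, 3, 5),
        ("RFLP", 40, 3, 10),
    ]

    hits: list[MarkerHit] = []
    clone_to_contig: dict[str, str | None] = {}
    serial = 0
    for mtype, count, n_contigs, n_clones in specs:
        for _ in range(count):
            marker_id = f"{mtype.lower()}_{serial:05d}"
            serial += 1
            clone_ids = [f"cl_{serial:05d}_{i}" for i in range(n_clones)]
            for i, cid in enumerate(clone_ids):
                if n_contigs == 0:
                    clone_to_contig[cid] = None
                else:
                    contig_index = min(i, n_contigs - 1)
                    clone_to_contig[cid] = f"ctg_{serial:05d}_{contig_index}"
                hits.append(MarkerHit(marker_id, mtype, cid))
    return hits, clone_to_contig
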