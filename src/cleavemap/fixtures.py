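"""Deterministic toy substrates for tests, examples and benchmarks.

The toy reference emulates a small cloning plasmid: ~2.7 kb circular,
carrying exactly one XmnI-type site (``GAANNNNTTC`` with the first two
degenerate bases A, so a blunt mid-site cut leaves a four-adenine
terminal run) and exactly one blunt ``GAG|CTC`` site (the ligation
junction then reads 5'-AGAGA-3' with a cassette starting GA).  The toy
cassette emulates the dT-tailed marker cassette: ~700 bp, beginning
``GA`` and ending with the junction ``T``.

Every 20-mer across both strands of reference and cassette is unique, so
exact anchor and flank searches have single loci by construction.
Builders retry derived sub-seeds until all constraints hold, making the
output a pure function of the requested seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .seqcore import CircularRef, iupac_find, revcomp
from .simulate import CassetteSpec, EnzymeModel, enzyme_nicks

__all__ = [
    "XMN_SITE",
    "XMN_POS",
    "BLUNT_SITE",
    "BLUNT_POS",
    "toy_fixtures",
    "geometry_enzymes",
    "make_fixtures",
]

REF_LEN = 2686  # pUC19-sized
CASSETTE_LEN = 700
XMN_SITE = "GAAAAGTTTC"  # GAANNNNTTC with NN = AA, NN = GT
XMN_POS = 600
BLUNT_SITE = "GAGCTC"
BLUNT_POS = 1200


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _all_kmers_unique(ref_seq: str, cassette_seq: str, k: int = 20) -> bool:
    kmers = []
    doubled = ref_seq + ref_seq[: k - 1]
    rc_doubled = revcomp(ref_seq) + revcomp(ref_seq)[: k - 1]
    for s in (doubled, rc_doubled):
        kmers.extend(s[i : i + k] for i in range(len(ref_seq)))
    for s in (cassette_seq, revcomp(cassette_seq)):
        kmers.extend(s[i : i + k] for i in range(len(s) - k + 1))
    return len(set(kmers)) == len(kmers)


def toy_fixtures(seed: int = 7):
    """Build the (reference, cassette) pair; deterministic in ``seed``."""
    for attempt in range(1000):
        rng = np.random.default_rng((seed, attempt))
        seq = list(_random_seq(rng, REF_LEN))
        seq[XMN_POS : XMN_POS + len(XMN_SITE)] = XMN_SITE
        seq[BLUNT_POS : BLUNT_POS + len(BLUNT_SITE)] = BLUNT_SITE
        ref_seq = "".join(seq)
        cas = list(_random_seq(rng, CASSETTE_LEN))
        cas[0:2] = "GA"
        cas[-1] = "T"
        cassette_seq = "".join(cas)
        ref = CircularRef("toy_ref", ref_seq)
        # both screens: single locus for each planted palindromic site
        if {p for p, _ in iupac_find("GAANNNNTTC", ref)} != {XMN_POS}:
            continue
        if {p for p, _ in iupac_find(BLUNT_SITE, ref)} != {BLUNT_POS}:
            continue
        if not _all_kmers_unique(ref_seq, cassette_seq):
            continue
        return ref, CassetteSpec(cassette_seq)
    raise RuntimeError("could not satisfy fixture constraints (unexpected)")


def geometry_enzymes(ref: CircularRef) -> list[EnzymeModel]:
    """Thirteen single-site models: blunt plus 5' and 3' overhangs of 1-6.

    Each recognises a 12-bp stretch of the reference verbatim (positions
    spread around the circle, one spanning the origin) with cut offsets
    producing the requested geometry; positions are nudged forward until
    the recognition sequence is unique on the substrate.
    """
    geometries = [("blunt", 0)] + [("5p", k) for k in range(1, 7)] + [
        ("3p", k) for k in range(1, 7)
    ]
    starts = [ref.L - 6] + [200 * (i + 1) for i in range(12)]
    doubled = ref.seq + ref.seq
    out = []
    for (kind, k), start in zip(geometries, starts):
        for shift in range(0, 200, 13):
            pos = (start + shift) % ref.L
            recog = doubled[pos : pos + 12]
            if kind == "5p":
                top, bottom = 6, 6 + k
            elif kind == "3p":
                top, bottom = 6, 6 - k
            else:
                top, bottom = 6, 6
            model = EnzymeModel(
                name=f"syn_{kind}{k}", recognition=recog,
                top_cut_offset=top, bottom_cut_offset=bottom,
            )
            if len(enzyme_nicks(model, ref)) == 1:
                out.append(model)
                break
        else:
            raise RuntimeError(f"no unique 12-mer near {start} (unexpected)")
    return out


def make_fixtures(outdir, seed: int = 7) -> dict[str, Path]:
    """Write the packaged toy dataset; identical bytes for identical seeds.

    Produces the toy reference and cassette FASTA, a TOML block of enzyme
    definitions covering blunt/5'/3' geometries plus the XmnI-type site,
    and a collision-model configuration.
    """
    from .io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, cassette = toy_fixtures(seed)
    paths = {
        "reference": outdir / "reference.fasta",
        "cassette": outdir / "cassette.fasta",
        "config": outdir / "toy_config.toml",
    }
    write_fasta(paths["reference"], [(ref.name, ref.seq)])
    write_fasta(paths["cassette"], [("toy_cassette", cassette.seq)])
    lines = [
        "# toy enzyme and event-model definitions (generated, seed-stable)",
        "",
        "[[enzymes]]",
        'name = "xmn_like"',
        'recognition = "GAANNNNTTC"',
        "top_cut_offset = 5",
        "bottom_cut_offset = 5",
        "",
        "[[enzymes]]",
        'name = "blunt_gagctc"',
        'recognition = "GAGCTC"',
        "top_cut_offset = 3",
        "bottom_cut_offset = 3",
        "",
    ]
    for enz in geometry_enzymes(ref):
        lines += [
            "[[enzymes]]",
            f'name = "{enz.name}"',
            f'recognition = "{enz.recognition}"',
            f"top_cut_offset = {enz.top_cut_offset}",
            f"bottom_cut_offset = {enz.bottom_cut_offset}",
            "",
        ]
    lines += [
        "[collision]",
        "d = 997",
        "origin = 300",
        "spread_p = 0.5",
        "min_half_spacing = 15",
        'mode = "symmetric"',
        "dissociation = 0.0",
        "",
    ]
    paths["config"].write_text("\n".join(lines))
    return paths
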