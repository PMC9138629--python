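"""Self-contained synthetic datasets with planted ground truth.

The generator emulates the data structure the analysis assumes: a small
transcriptome; a panel of miRNAs; two-condition (sun/shade), two-replicate
small-RNA libraries with negative-binomial counts around planted fold
changes (including uniquely expressed miRNAs); degradome tag profiles with
a planted peak at the expected cleavage position over uniform background;
and a target log2FC table concordant with the planted regulation classes.

Planted target sites are built by reverse-complementing the miRNA into the
transcript and then mutating site columns at chosen miRNA positions until
the designed duplex penalty is met exactly (re-verified with the aligner).
For a transcript carrying a planted site, background degradome tags are
drawn over the non-diagnostic positions, so the diagnostic position's
expected share of the transcript's tags is exactly ``peak_fraction``.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rnautil import RNA_BASES, reverse_complement, to_rna
from .targets import AllenParams, DEFAULT_PARAMS, align_duplex

__all__ = [
    "SimulationConfig",
    "Bundle",
    "RecoveryReport",
    "generate",
    "recover",
    "write_bundle",
    "load_bundle",
]

_MIR_CLASS_CYCLE = ("up", "down", "neutral", "unique_shade", "unique_sun")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic run; the defaults are the study design
    emulated at desk scale (2 conditions x 2 replicates)."""

    seed: int
    n_transcripts: int = 12
    transcript_length: tuple[int, int] = (400, 700)
    n_mirnas: int = 8
    mirna_length: tuple[int, int] = (20, 22)
    n_planted_pairs: int | None = None  # None = one site per miRNA
    planted_scores: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    mir_classes: tuple[str, ...] = _MIR_CLASS_CYCLE
    mir_log2fc_magnitude: float = 2.0
    target_log2fc_magnitude: float = 1.0
    target_noise_sd: float = 0.05
    peak_fraction: float = 0.9
    site_tag_total: int = 40
    background_tag_rate: float = 0.02  # expected background tags per nt
    tag_length: int = 20
    depth: float = 200.0  # mean small-RNA reads per miRNA per library
    dispersion: float = 10.0  # negative-binomial size
    n_replicates: int = 2
    n_noise_tags: int = 15  # non-miRNA small-RNA species per library
    low_quality_fraction: float = 0.05
    short_read_fraction: float = 0.05
    read_quality: int = 35
    allen_params: AllenParams = DEFAULT_PARAMS


@dataclass
class Bundle:
    """In-memory dataset bundle plus its ground truth."""

    config: SimulationConfig
    transcripts: dict[str, str]
    mirnas: dict[str, str]
    reads: dict[str, list[tuple[str, list[int]]]]  # library -> (seq, phred)
    conditions: dict[str, str]  # library -> sun | shade
    degradome_tags: list[tuple[str, int]]
    target_table: pd.DataFrame  # transcript_id, log2fc
    truth: pd.DataFrame


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length))


_NON_PAIRING = {
    "A": "ACG",  # site bases that neither WC- nor wobble-pair the miR base
    "C": "ACU",
    "G": "AG",
    "U": "CU",
}


def _plant_site(
    rng: np.random.Generator,
    mirna: str,
    designed_score: float,
    params: AllenParams,
    max_attempts: int = 50,
) -> str:
    """A site sequence whose optimal duplex penalty equals the design.

    Starts from the exact reverse complement and mutates site columns:
    a mismatch at a non-doubled miRNA position costs 1, at a doubled
    position 2, and a G:U wobble at a non-doubled position supplies the
    0.5 fraction.
    """
    L = len(mirna)
    core_lo, core_hi = params.core_start, params.core_end
    nd_positions = [p for p in range(1, L + 1) if not core_lo <= p <= core_hi]
    d_positions = [p for p in range(1, L + 1) if core_lo <= p <= core_hi]
    frac = designed_score - int(designed_score)
    if frac not in (0.0, 0.5):
        raise ConfigError(f"designed score {designed_score} is not a multiple of 0.5")
    max_score = len(nd_positions) * 1.0 + len(d_positions) * 2.0
    if designed_score > max_score:
        raise ConfigError(
            f"designed score {designed_score} exceeds the maximum {max_score} "
            f"achievable by point mutations"
        )

    for _ in range(max_attempts):
        site = list(reverse_complement(mirna))
        used: set[int] = set()

        def site_idx(p: int) -> int:
            return L - p  # gapless column of miRNA position p

        if frac:
            wob = [p for p in nd_positions if mirna[p - 1] in "GU"]
            if not wob:
                raise ConfigError(
                    "half-point designed score needs a G or U miRNA base at a "
                    "non-doubled position"
                )
            p = int(rng.choice(wob))
            site[site_idx(p)] = "U" if mirna[p - 1] == "G" else "G"
            used.add(p)

        r = int(designed_score)
        nd_free = [p for p in nd_positions if p not in used]
        rng.shuffle(nd_free)
        d_free = list(d_positions)
        rng.shuffle(d_free)
        # split the integer budget between doubled (cost 2) and non-doubled
        # (cost 1) mismatches; vary the split across attempts so a spread
        # exists for which the optimal alignment keeps the planted register
        splits = [
            (a, r - 2 * a)
            for a in range(min(r // 2, len(d_free)) + 1)
            if 0 <= r - 2 * a <= len(nd_free)
        ]
        if not splits:
            raise ConfigError(f"designed score {designed_score} infeasible")
        n_double, n_single = splits[int(rng.integers(len(splits)))]
        for p in d_free[:n_double]:
            site[site_idx(p)] = str(rng.choice(list(_NON_PAIRING[mirna[p - 1]])))
        for p in nd_free[:n_single]:
            site[site_idx(p)] = str(rng.choice(list(_NON_PAIRING[mirna[p - 1]])))

        planted = "".join(site)
        aln = align_duplex(mirna, planted, params, enforce_bounds=False)
        if aln.allen_score == designed_score:
            return planted
    raise ConfigError(
        f"could not realize designed score {designed_score} for miRNA {mirna}"
    )


def _target_class_for(mir_class: str, idx: int) -> tuple[str, str]:
    """(target class, interaction class) planted contrasting with the miR."""
    if mir_class == "up":
        return "down", "repression_by_induced_mir"
    if mir_class == "down":
        return "up", "derepression_by_reduced_mir"
    if mir_class == "unique_shade":
        return "down", "shade_specific_silencing"
    if mir_class == "unique_sun":
        return "up", "absence_release"
    # neutral miRNA: alternate target direction
    return ("up" if idx % 2 == 0 else "down"), "differential_binding_candidate"


def _nb_draw(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def generate(config: SimulationConfig) -> Bundle:
    """Deterministic dataset bundle for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n_pairs = (
        config.n_mirnas if config.n_planted_pairs is None else config.n_planted_pairs
    )
    if n_pairs > min(config.n_mirnas, config.n_transcripts):
        raise ConfigError("more planted pairs than miRNAs or transcripts")

    lo, hi = config.transcript_length
    transcripts = {
        f"TX{i + 1:03d}": _random_rna(rng, int(rng.integers(lo, hi + 1)))
        for i in range(config.n_transcripts)
    }
    mlo, mhi = config.mirna_length
    mirnas = {
        f"mir{i + 1:03d}": _random_rna(rng, int(rng.integers(mlo, mhi + 1)))
        for i in range(config.n_mirnas)
    }

    mir_ids = list(mirnas)
    tx_ids = list(transcripts)
    truth_rows = []
    site_cs: dict[str, int] = {}  # transcript -> diagnostic position
    for i in range(n_pairs):
        mid, tid = mir_ids[i], tx_ids[i]
        mseq = mirnas[mid]
        L = len(mseq)
        designed = config.planted_scores[i % len(config.planted_scores)]
        site = _plant_site(rng, mseq, designed, config.allen_params)
        tlen = len(transcripts[tid])
        margin = config.tag_length + 12
        t_start = int(rng.integers(margin, tlen - L - margin))
        tseq = transcripts[tid]
        transcripts[tid] = tseq[: t_start - 1] + site + tseq[t_start - 1 + L :]
        t_stop = t_start + L - 1
        aln = align_duplex(
            mseq, site, config.allen_params, transcript_id=tid,
            t_start=t_start, enforce_bounds=False,
        )
        assert aln.allen_score == designed
        cs = aln.expected_cs
        site_cs[tid] = cs
        mir_class = config.mir_classes[i % len(config.mir_classes)]
        mir_lfc = {
            "up": config.mir_log2fc_magnitude,
            "down": -config.mir_log2fc_magnitude,
            "neutral": 0.0,
            "unique_shade": config.mir_log2fc_magnitude,
            "unique_sun": -config.mir_log2fc_magnitude,
        }[mir_class]
        t_class, interaction = _target_class_for(mir_class, i)
        t_lfc = (
            config.target_log2fc_magnitude
            if t_class == "up"
            else -config.target_log2fc_magnitude
        )
        truth_rows.append(
            {
                "mirna_id": mid,
                "transcript_id": tid,
                "t_start": t_start,
                "t_stop": t_stop,
                "expected_cs": cs,
                "designed_score": designed,
                "mir_class": mir_class,
                "mir_log2fc": mir_lfc,
                "target_class": t_class,
                "target_log2fc": t_lfc,
                "interaction_class": interaction,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "mirna_id", "transcript_id", "t_start", "t_stop", "expected_cs",
            "designed_score", "mir_class", "mir_log2fc", "target_class",
            "target_log2fc", "interaction_class",
        ],
    )

    # --- degradome tags ---------------------------------------------------
    degradome: list[tuple[str, int]] = []
    for tid, tseq in transcripts.items():
        tlen = len(tseq)
        max_start = tlen - config.tag_length + 1
        cs = site_cs.get(tid)
        if cs is not None and config.site_tag_total > 0:
            peak = int(round(config.peak_fraction * config.site_tag_total))
            if peak > 0:
                degradome.append((tseq[cs - 1 : cs - 1 + config.tag_length], peak))
            for _ in range(config.site_tag_total - peak):
                pos = int(rng.integers(1, max_start + 1))
                while pos == cs:
                    pos = int(rng.integers(1, max_start + 1))
                degradome.append((tseq[pos - 1 : pos - 1 + config.tag_length], 1))
        n_bg = int(rng.poisson(config.background_tag_rate * tlen))
        for _ in range(n_bg):
            pos = int(rng.integers(1, max_start + 1))
            if cs is not None and pos == cs:
                continue
            degradome.append((tseq[pos - 1 : pos - 1 + config.tag_length], 1))

    # --- small-RNA libraries ---------------------------------------------
    libraries = [
        f"{cond}_{r + 1}"
        for cond in ("sun", "shade")
        for r in range(config.n_replicates)
    ]
    conditions = {lib: lib.split("_")[0] for lib in libraries}
    class_by_mir = {
        row["mirna_id"]: row["mir_class"] for _, row in truth.iterrows()
    }
    lfc_by_mir = {
        row["mirna_id"]: row["mir_log2fc"] for _, row in truth.iterrows()
    }
    noise_tags = [
        _random_rna(rng, int(rng.integers(20, 25))) for _ in range(config.n_noise_tags)
    ]
    q = config.read_quality
    reads: dict[str, list[tuple[str, list[int]]]] = {lib: [] for lib in libraries}
    for lib in libraries:
        cond = conditions[lib]
        for mid in mir_ids:
            cls = class_by_mir.get(mid, "neutral")
            lfc = lfc_by_mir.get(mid, 0.0)
            if cls == "unique_shade" and cond == "sun":
                continue
            if cls == "unique_sun" and cond == "shade":
                continue
            if cls in ("unique_shade", "unique_sun"):
                mean = config.depth
            else:
                sign = 1.0 if cond == "shade" else -1.0
                mean = config.depth * 2.0 ** (sign * lfc / 2.0)
            count = _nb_draw(rng, mean, config.dispersion)
            seq = mirnas[mid]
            reads[lib].extend((seq, [q] * len(seq)) for _ in range(count))
        for tag in noise_tags:
            count = _nb_draw(rng, config.depth / 10.0, config.dispersion)
            reads[lib].extend((tag, [q] * len(tag)) for _ in range(count))
        # reads the cleaning stage must reject
        n_total = max(len(reads[lib]), 1)
        for _ in range(int(config.low_quality_fraction * n_total)):
            seq = _random_rna(rng, 21)
            qual = [q] * 21
            qual[int(rng.integers(0, 21))] = 20
            reads[lib].append((seq, qual))
        for _ in range(int(config.short_read_fraction * n_total)):
            seq = _random_rna(rng, int(rng.integers(10, 16)))
            reads[lib].append((seq, [q] * len(seq)))

    # --- target expression table ------------------------------------------
    planted_lfc = {
        row["transcript_id"]: row["target_log2fc"] for _, row in truth.iterrows()
    }
    target_rows = []
    for tid in tx_ids:
        if tid in planted_lfc:
            fc = planted_lfc[tid] + rng.normal(0.0, config.target_noise_sd)
        else:
            fc = rng.normal(0.0, 0.1)
        target_rows.append({"transcript_id": tid, "log2fc": float(fc)})
    target_table = pd.DataFrame(target_rows, columns=["transcript_id", "log2fc"])

    return Bundle(
        config=config,
        transcripts=transcripts,
        mirnas=mirnas,
        reads=reads,
        conditions=conditions,
        degradome_tags=degradome,
        target_table=target_table,
        truth=truth,
    )


@dataclass
class RecoveryReport:
    """Pipeline output compared against the bundle's planted truth."""

    n_planted: int
    n_recovered: int
    sensitivity: float
    false_pairs: list[tuple[str, str]]
    n_false_strict: int  # false pairs at category 0 with p <= 0.05
    shortlist: pd.DataFrame
    pairs: pd.DataFrame


def recover(bundle: Bundle, params=None) -> RecoveryReport:
    """Run the full pipeline on a bundle and score it against the truth.

    Sensitivity is the fraction of planted contrasting pairs present in
    the shortlist; a false pair is a shortlist entry that was not planted.
    """
    from .integrate import pairs_to_frame
    from .pipeline import RunParams, run_bundle

    if params is None:
        params = RunParams(seed=bundle.config.seed)
    result = run_bundle(bundle, params)
    planted = {
        (row["mirna_id"], row["transcript_id"])
        for _, row in bundle.truth.iterrows()
        if row["interaction_class"] != "discordant"
    }
    short = result.shortlist
    recovered = set(zip(short["mirna"], short["target_id"])) if len(short) else set()
    hits_found = planted & recovered
    false_pairs = sorted(recovered - planted)
    strict = 0
    for _, row in short.iterrows():
        key = (row["mirna"], row["target_id"])
        if key not in planted and row["category"] == 0 and row["p_value"] <= 0.05:
            strict += 1
    sensitivity = len(hits_found) / len(planted) if planted else float("nan")
    return RecoveryReport(
        n_planted=len(planted),
        n_recovered=len(recovered),
        sensitivity=sensitivity,
        false_pairs=false_pairs,
        n_false_strict=strict,
        shortlist=short,
        pairs=pairs_to_frame(result.pairs),
    )


def derive_seed(master_seed: int, *labels: str) -> int:
    """Stable sub-stream seed below 2^31 for a labelled component."""
    h = zlib.crc32("/".join(labels).encode())
    return (master_seed * 1_000_003 + h) % (2**31)


# ---------------------------------------------------------------------------
# serialization


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def write_bundle(bundle: Bundle, outdir: str | Path) -> Path:
    """Write a bundle to disk (FASTA/FASTQ/TSV + JSON manifest)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(out / "transcriptome.fasta", bundle.transcripts)
    _write_fasta(out / "mirnas.fasta", bundle.mirnas)
    for lib, lib_reads in bundle.reads.items():
        with open(out / f"smallrna_{lib}.fastq", "w") as fh:
            for i, (seq, qual) in enumerate(lib_reads):
                qstr = "".join(chr(q + 33) for q in qual)
                fh.write(f"@{lib}_read{i + 1}\n{seq}\n+\n{qstr}\n")
    with open(out / "degradome.fasta", "w") as fh:
        for i, (seq, count) in enumerate(bundle.degradome_tags):
            fh.write(f">deg{i + 1}_x{count}\n{seq}\n")
    bundle.target_table.to_csv(out / "target_log2fc.tsv", sep="\t", index=False)
    bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(bundle.config)
    cfg["allen_params"] = dataclasses.asdict(bundle.config.allen_params)
    manifest = {
        "config": cfg,
        "conditions": bundle.conditions,
        "files": {
            "transcriptome": "transcriptome.fasta",
            "mirnas": "mirnas.fasta",
            "degradome": "degradome.fasta",
            "target_log2fc": "target_log2fc.tsv",
            "truth": "truth.tsv",
            "smallrna": {
                lib: f"smallrna_{lib}.fastq" for lib in bundle.reads
            },
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def _read_fasta(path: Path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        records[name] = "".join(parts)
    return records


def load_bundle(path: str | Path) -> Bundle:
    """Round-trip a bundle written by :func:`write_bundle`."""
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    cfg_dict["allen_params"] = AllenParams(**cfg_dict["allen_params"])
    for key in ("transcript_length", "mirna_length", "planted_scores", "mir_classes"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SimulationConfig(**cfg_dict)
    reads: dict[str, list[tuple[str, list[int]]]] = {}
    for lib, fname in manifest["files"]["smallrna"].items():
        lib_reads = []
        with open(path / fname) as fh:
            lines = [l.rstrip("\n") for l in fh]
        for i in range(0, len(lines) - 3, 4):
            seq = lines[i + 1]
            qual = [ord(c) - 33 for c in lines[i + 3]]
            lib_reads.append((seq, qual))
        reads[lib] = lib_reads
    deg_fa = _read_fasta(path / manifest["files"]["degradome"])
    degradome = []
    for header, seq in deg_fa.items():
        count = int(header.rsplit("_x", 1)[1]) if "_x" in header else 1
        degradome.append((seq, count))
    return Bundle(
        config=config,
        transcripts=_read_fasta(path / manifest["files"]["transcriptome"]),
        mirnas=_read_fasta(path / manifest["files"]["mirnas"]),
        reads=reads,
        conditions=dict(manifest["conditions"]),
        degradome_tags=degradome,
        target_table=pd.read_csv(path / manifest["files"]["target_log2fc"], sep="\t"),
        truth=pd.read_csv(path / manifest["files"]["truth"], sep="\t"),
    )
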