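"""Readers, writers, run configuration and the end-to-end runners.

Canonical dialects (CSV with header row; TSV accepted):

* **Tetrad phenotype table** -- one row per tetrad, columns ``spore1`` ..
  ``spore4`` holding 3-bit fluorophore strings (e.g. ``101``), optional
  ``genotype``/``plant`` columns.
* **Class-count table** -- columns ``genotype``, optional ``plant``,
  letters ``A`` .. ``L`` and ``n``; ``n`` must equal the class-count sum.
  A letter remap file (columns ``letter, ditype_i1, ditype_i2``) can
  redefine foreign letter conventions in terms of per-interval ditypes; the
  package's canonical letter key is emitted alongside every output.
* **Foci table** -- ``kind, genotype, treatment, cell_id, count``.
* **Bivalent table** -- ``genotype, cell_id, ring, ring3, rod,
  univalent_pairs``.

Readers validate and reject malformed rows with line numbers rather than
coercing them.  Every runner records the seed and a config hash so
stochastic outputs are bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    TetradClassCounts,
    canonical_ditype_map,
    classify_sample,
    enumerate_classes,
    tabulate,
)
from .errors import ConfigError, DataError
from .interference import (
    coc_interference,
    per_plant_and_pooled,
    perkins_distance,
    recombinant_frequencies,
    ztest_interference,
    ztest_proportions,
)
from .markers import IntervalPairMap
from .simulate import PathwayParams, simulate_sample

_LETTERS = [c.label for c in enumerate_classes()]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Validated configuration for the reproduce/compare runners."""

    seed: int = 0
    output_dir: str = "results"
    inputs: list[dict] = field(default_factory=list)
    comparisons: list[list[str]] = field(default_factory=list)
    estimator: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for entry in cfg.inputs:
            p = Path(entry.get("path", ""))
            if not p.exists():
                raise ConfigError(f"input file {p} does not exist")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_letter_remap(path: str | Path) -> dict[str, tuple[str, str]]:
    """Letter -> (I1 ditype, I2 ditype) remap for foreign class conventions."""
    df = _read_table(path)
    required = {"letter", "ditype_i1", "ditype_i2"}
    if not required.issubset(df.columns):
        raise DataError(f"remap file needs columns {sorted(required)}")
    remap = {}
    for i, row in df.iterrows():
        d1, d2 = row["ditype_i1"].strip(), row["ditype_i2"].strip()
        if d1 not in "PTN" or d2 not in "PTN":
            raise DataError(f"remap line {i + 2}: ditypes must be P, T or N")
        remap[row["letter"].strip()] = (d1, d2)
    return remap


def _canonical_letter(d1: str, d2: str) -> str:
    """First canonical class with the given ditype pair (subtype-agnostic)."""
    for c in enumerate_classes():
        if c.ditypes == (d1, d2):
            return c.label
    raise DataError(f"no canonical class with ditypes ({d1}, {d2})")


# ---------------------------------------------------------------------------
# tetrad tables


def read_tetrad_table(path: str | Path, remap: dict | None = None):
    """Read either a raw tetrad phenotype table or a class-count table.

    Returns ``("tetrads", spores_array, meta_df)`` or
    ``("class_counts", [TetradClassCounts, ...])`` depending on the layout.
    Malformed rows raise :class:`DataError` naming the file line.
    """
    df = _read_table(path)
    spore_cols = [f"spore{i}" for i in range(1, 5)]
    if all(c in df.columns for c in spore_cols):
        return ("tetrads", *_parse_tetrad_rows(df, spore_cols, path))
    letter_cols = [c for c in df.columns if len(c) == 1 and c.isalpha()
                   and c.isupper()]
    if letter_cols:
        return ("class_counts", _parse_class_counts(df, path, remap))
    raise DataError(
        f"{path}: expected either spore1..spore4 columns or class-count "
        "letter columns"
    )


def _parse_tetrad_rows(df, spore_cols, path):
    spores = np.zeros((len(df), 4, 3), dtype=np.uint8)
    for j, col in enumerate(spore_cols):
        for i, val in enumerate(df[col]):
            s = val.strip()
            if len(s) != 3 or any(ch not in "01" for ch in s):
                raise DataError(
                    f"{path} line {i + 2}: spore phenotype {val!r} is not a "
                    "3-bit string"
                )
            spores[i, j] = [int(ch) for ch in s]
    meta = df.drop(columns=spore_cols)
    return spores, meta


def _parse_class_counts(df, path, remap):
    letters = [c for c in df.columns if len(c) == 1 and c.isalpha() and c.isupper()]
    out = []
    for i, row in df.iterrows():
        counts: dict[str, int] = {k: 0 for k in _LETTERS}
        for letter in letters:
            val = row[letter].strip() or "0"
            try:
                v = int(val)
            except ValueError:
                raise DataError(
                    f"{path} line {i + 2}: count {val!r} in column "
                    f"{letter} is not an integer"
                ) from None
            if v < 0:
                raise DataError(f"{path} line {i + 2}: negative count")
            if remap is not None:
                if letter not in remap:
                    raise DataError(
                        f"{path} line {i + 2}: letter {letter} missing from remap"
                    )
                target = _canonical_letter(*remap[letter])
            else:
                if letter not in counts:
                    raise DataError(
                        f"{path} line {i + 2}: unknown class letter {letter}"
                    )
                target = letter
            counts[target] += v
        cc = TetradClassCounts(
            genotype=row.get("genotype", "unknown"),
            plant=row.get("plant") or None,
            counts=counts,
        )
        if "n" in df.columns and row["n"].strip():
            declared = int(row["n"])
            if declared != cc.n:
                raise DataError(
                    f"{path} line {i + 2}: declared n={declared} but class "
                    f"counts sum to {cc.n}"
                )
        out.append(cc)
    return out


def write_tetrad_csv(spores: np.ndarray, path: str | Path,
                     genotype: str = "simulated") -> None:
    """Write raw tetrads with their class labels (canonical letter key in header)."""
    labels = classify_sample(spores)
    key = "; ".join(f"{k}={v[0]}{v[1]}" for k, v in canonical_ditype_map().items())
    df = pd.DataFrame(
        {
            "genotype": genotype,
            **{
                f"spore{j + 1}": ["".join(map(str, t[j])) for t in spores]
                for j in range(4)
            },
            "class": labels,
        }
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# class letter key (ditype I1, ditype I2): {key}\n")
        df.to_csv(fh, index=False)


def write_class_counts_csv(tables: list[TetradClassCounts],
                           path: str | Path) -> None:
    key = "; ".join(f"{k}={v[0]}{v[1]}" for k, v in canonical_ditype_map().items())
    rows = []
    for t in tables:
        row = {"genotype": t.genotype, "plant": t.plant or ""}
        row.update(t.counts)
        row["n"] = t.n
        rows.append(row)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# class letter key (ditype I1, ditype I2): {key}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_tetrad_csv_with_comments(path: str | Path, remap=None):
    """Read the package's own CSVs (skipping the letter-key comment line)."""
    text = Path(path).read_text().splitlines()
    body = "\n".join(line for line in text if not line.startswith("#"))
    import io as _io

    df = pd.read_csv(_io.StringIO(body), dtype=str, keep_default_na=False)
    tmp = Path(path).with_suffix(".tmp_nocomment.csv")
    try:
        df.to_csv(tmp, index=False)
        return read_tetrad_table(tmp, remap=remap)
    finally:
        tmp.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# foci and bivalent tables


def read_foci_table(path: str | Path):
    from .cyto import FociRecord

    df = _read_table(path)
    required = {"kind", "genotype", "treatment", "cell_id", "count"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            count = int(row["count"])
        except ValueError:
            raise DataError(
                f"{path} line {i + 2}: count {row['count']!r} is not an integer"
            ) from None
        records.append(
            FociRecord(cell_id=row["cell_id"], genotype=row["genotype"],
                       count=count, kind=row["kind"],
                       treatment=row["treatment"])
        )
    return records


def read_bivalent_table(path: str | Path):
    from .cyto import BivalentCell

    df = _read_table(path)
    required = {"genotype", "cell_id", "ring", "ring3", "rod", "univalent_pairs"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    cells = []
    for i, row in df.iterrows():
        try:
            vals = {k: int(row[k]) for k in ("ring", "ring3", "rod",
                                             "univalent_pairs")}
        except ValueError:
            raise DataError(f"{path} line {i + 2}: non-integer shape count") \
                from None
        cells.append(BivalentCell(cell_id=row["cell_id"],
                                  genotype=row["genotype"], **vals))
    return cells


def write_foci_csv(records, path: str | Path) -> None:
    pd.DataFrame(
        {"kind": r.kind, "genotype": r.genotype, "treatment": r.treatment,
         "cell_id": r.cell_id, "count": r.count}
        for r in records
    ).to_csv(path, index=False)


def write_bivalent_csv(cells, path: str | Path) -> None:
    pd.DataFrame(
        {"genotype": c.genotype, "cell_id": c.cell_id, "ring": c.ring,
         "ring3": c.ring3, "rod": c.rod, "univalent_pairs": c.univalent_pairs}
        for c in cells
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixtures


def generate_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write small deterministic example inputs (two genotypes, known truth).

    The "interfering" genotype simulates pure Class I crossovers with strong
    interference (nu = 10); the "poisson" genotype pure Class II.  Also
    emits foci and bivalent tables from the labelled synthetic
    reconstructions.
    """
    from . import synthetic_tables
    from .simulate import PathwayParams

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    imap = IntervalPairMap(d1=10.0, d2=10.0)
    scenarios = {
        "interfering": PathwayParams(nu=10.0, frac_class2=0.0),
        "poisson": PathwayParams(nu=1.0, frac_class2=1.0),
    }
    files = {}
    tables = []
    for i, (name, params) in enumerate(scenarios.items()):
        sample = simulate_sample(800, imap, params, seed=seed + i)
        p = outdir / f"tetrads_{name}.csv"
        write_tetrad_csv(sample.spores, p, genotype=name)
        files[f"tetrads_{name}"] = p
        for plant in range(4):
            chunk = sample.spores[plant * 200:(plant + 1) * 200]
            tables.append(tabulate(chunk, genotype=name, plant=f"p{plant + 1}"))
    p = outdir / "class_counts.csv"
    write_class_counts_csv(tables, p)
    files["class_counts"] = p
    p = outdir / "synthetic_foci.csv"
    write_foci_csv(synthetic_tables.foci_records(), p)
    files["foci"] = p
    p = outdir / "synthetic_bivalents.csv"
    write_bivalent_csv(synthetic_tables.bivalent_cells(), p)
    files["bivalents"] = p
    return files


# ---------------------------------------------------------------------------
# runners


@dataclass
class ReproReport:
    """End-to-end report: estimates, comparisons, and the audit trail."""

    seed: int
    config_digest: str
    version: str
    estimates: pd.DataFrame
    comparisons: pd.DataFrame
    class_tables: pd.DataFrame
    headline: dict | None = None
    exclusions: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config_digest": self.config_digest,
                "version": self.version,
                "estimates": self.estimates.to_dict(orient="records"),
                "comparisons": self.comparisons.to_dict(orient="records"),
                "headline": self.headline,
                "exclusions": self.exclusions,
            },
            indent=2,
            default=float,
        )


def reproduce_interference(config: RunConfig) -> ReproReport:
    """Distances, CoC/interference and genotype Z-tests from class-count CSVs.

    Each input entry is ``{interval: <name>, path: <csv>, remap: <csv,
    optional>}``.  Estimates are reported from pooled counts with the
    per-plant mean alongside whenever plants are present.
    """
    est_rows, cls_rows, exclusions = [], [], []
    pooled_by_key: dict[tuple[str, str], TetradClassCounts] = {}
    for entry in config.inputs:
        interval = entry.get("interval", "interval")
        remap = read_letter_remap(entry["remap"]) if entry.get("remap") else None
        kind, *payload = read_tetrad_csv_with_comments(entry["path"],
                                                       remap=remap)
        if kind == "tetrads":
            spores, meta = payload
            genos = meta["genotype"] if "genotype" in meta else ["unknown"] * len(spores)
            tables = [
                tabulate(spores[np.asarray(genos) == g], genotype=g)
                for g in sorted(set(genos))
            ]
        else:
            tables = payload[0]
        by_geno: dict[str, list[TetradClassCounts]] = {}
        for t in tables:
            by_geno.setdefault(t.genotype, []).append(t)
        for genotype, plants in by_geno.items():
            summary = per_plant_and_pooled(plants)
            d1, d2 = summary.pooled_distance
            est = summary.pooled_coc
            est_rows.append(
                {
                    "interval": interval,
                    "genotype": genotype,
                    "n": est.n,
                    "distance_i1_cM": d1.distance,
                    "distance_i1_se": d1.se,
                    "distance_i2_cM": d2.distance,
                    "distance_i2_se": d2.se,
                    "f1": est.f1,
                    "f2": est.f2,
                    "f12": est.f12,
                    "coc": est.coc,
                    "interference": est.interference,
                    "interference_se": est.se_interference,
                    "per_plant_mean_interference": summary.mean_interference,
                    "no_doubles": est.no_doubles,
                    "flagged": sum(p.flagged for p in plants),
                }
            )
            exclusions.extend(
                {"interval": interval, "genotype": genotype, "plant": p}
                for p in summary.excluded
            )
            pooled = plants[0]
            for extra in plants[1:]:
                pooled = pooled + extra
            pooled_by_key[(interval, genotype)] = pooled
            row = {"interval": interval, "genotype": genotype}
            row.update(pooled.counts)
            row["n"] = pooled.n
            cls_rows.append(row)

    cmp_rows = []
    for g1, g2 in config.comparisons:
        for (interval, genotype), counts1 in pooled_by_key.items():
            if genotype != g1 or (interval, g2) not in pooled_by_key:
                continue
            counts2 = pooled_by_key[(interval, g2)]
            for iv_index in (1, 2):
                t1, n1 = counts1.t_n_counts(iv_index)[0] + counts1.t_n_counts(iv_index)[1], counts1.n
                t2, n2 = counts2.t_n_counts(iv_index)[0] + counts2.t_n_counts(iv_index)[1], counts2.n
                res = ztest_proportions(t1, n1, t2, n2)
                cmp_rows.append(
                    {"interval": interval, "sub_interval": iv_index,
                     "test": "recombinant frequency Z", "genotype_1": g1,
                     "genotype_2": g2, "statistic": res.statistic,
                     "p_value": res.p_value}
                )
            res = ztest_interference(counts1, counts2)
            cmp_rows.append(
                {"interval": interval, "sub_interval": "pair",
                 "test": "interference Z", "genotype_1": g1,
                 "genotype_2": g2, "statistic": res.statistic,
                 "p_value": res.p_value}
            )

    return ReproReport(
        seed=config.seed,
        config_digest=config.digest(),
        version=__version__,
        estimates=pd.DataFrame(est_rows),
        comparisons=pd.DataFrame(cmp_rows),
        class_tables=pd.DataFrame(cls_rows),
        exclusions=exclusions,
    )


def headline_simulation(config: RunConfig) -> dict:
    """The in-silico pathway re-channeling experiment.

    Two scenarios with equal total crossover rate but different Class II
    fractions are simulated; the report gives, per scenario, the mean Class
    I crossover number per meiosis (MLH1-focus proxy), per-interval
    crossover frequencies presented as Perkins genetic distances, and
    interference, together with the between-scenario differences and their
    Monte-Carlo standard errors.  Re-channeling Class II into Class I must
    raise interference and the Class I count while leaving the genetic
    distances unchanged.  (The raw recombinant-tetrad fractions are also
    reported but are not exactly conserved: re-channeling preserves the
    mean crossover number, not the full count distribution, so P(>=1 CO)
    shifts by a few permil; the genetic distance tracks the mean and is the
    quantity the experiment holds constant.)
    """
    sim = config.simulation
    scenarios = sim.get("scenarios")
    if not scenarios or len(scenarios) != 2:
        raise ConfigError("headline simulation needs exactly two scenarios")
    rates = [s.get("total_rate", 2.0) for s in scenarios]
    if rates[0] != rates[1]:
        raise ConfigError(
            "scenarios must share total_rate: the experiment holds total "
            f"crossover number constant (got {rates})"
        )
    n = int(sim.get("n_tetrads", 50_000))
    imap = IntervalPairMap(d1=sim.get("d1", 10.0), d2=sim.get("d2", 10.0))
    out = {"n_tetrads": n, "scenarios": []}
    ests = []
    for i, sc in enumerate(scenarios):
        params = PathwayParams(
            nu=sc.get("nu", 8.0),
            frac_class2=sc["frac_class2"],
            total_rate=sc.get("total_rate", 2.0),
        )
        sample = simulate_sample(n, imap, params, seed=config.seed + i)
        counts = tabulate(sample, genotype=sc.get("name", f"scenario{i}"))
        est = coc_interference(counts)
        f1, f2, _ = recombinant_frequencies(counts)
        d1 = perkins_distance(counts, 1)
        d2 = perkins_distance(counts, 2)
        ests.append((est, d1, d2, sample))
        out["scenarios"].append(
            {
                "name": sc.get("name", f"scenario{i}"),
                "frac_class2": params.frac_class2,
                "nu": params.nu,
                "total_rate": params.total_rate,
                "mean_class1_per_meiosis": float(sample.class1_counts.mean()),
                "mean_class2_per_meiosis": float(sample.class2_counts.mean()),
                "f1": f1,
                "f2": f2,
                "distance_i1_cM": d1.distance,
                "distance_i1_se": d1.se,
                "distance_i2_cM": d2.distance,
                "distance_i2_se": d2.se,
                "interference": est.interference,
                "interference_se": est.se_interference,
            }
        )
    (e1, d1a, d2a, s1), (e2, d1b, d2b, s2) = ests
    out["delta"] = {
        "interference": e2.interference - e1.interference,
        "interference_se": float(
            np.sqrt(e1.se_interference**2 + e2.se_interference**2)
        ),
        "class1_per_meiosis": float(
            s2.class1_counts.mean() - s1.class1_counts.mean()
        ),
        "distance_i1_cM": d1b.distance - d1a.distance,
        "distance_i1_se": float(np.hypot(d1a.se, d1b.se)),
        "distance_i2_cM": d2b.distance - d2a.distance,
        "distance_i2_se": float(np.hypot(d2a.se, d2b.se)),
    }
    return out


def write_run_log(outdir: str | Path, config: RunConfig) -> Path:
    """Plain-text log: config hash, seed, package version."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = outdir / "run.log"
    log.write_text(
        f"meiocross {__version__}\nseed: {config.seed}\n"
        f"config: {config.digest()}\n"
    )
    return log
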