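"""Readers/writers, domain-type validation and the CLI entry points."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from cresig import io as cio
from cresig.cli import main as cli_main
from cresig.model import (
    CresigError,
    ExpressionMatrix,
    GeneSetCollection,
    RunConfig,
    TrapList,
    validate_deg_table,
)

from conftest import make_deg_table


class TestExpressionIO:
    def test_toy_file_shape(self, tmp_path):
        (tmp_path / "x.tsv").write_text(
            "gene\ts1\ts2\ts3\ts4\n"
            "g1\t1\t2\t3\t4\n"
            "g2\t0.5\t0.5\t0.5\t0.5\n"
            "g3\t-1\t0\t1\t2\n"
        )
        (tmp_path / "cond.tsv").write_text(
            "sample\tcondition\ns1\tCT\ns2\tCT\ns3\tT\ns4\tT\n"
        )
        expr = cio.read_expression(tmp_path / "x.tsv", tmp_path / "cond.tsv")
        assert expr.values.shape == (3, 4)
        assert expr.samples_of("T") == ["s3", "s4"]

    def test_duplicate_gene_rejected(self, tmp_path):
        (tmp_path / "x.tsv").write_text("gene\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
        (tmp_path / "cond.tsv").write_text("sample\tcondition\ns1\tA\ns2\tB\n")
        with pytest.raises(CresigError, match="g1"):
            cio.read_expression(tmp_path / "x.tsv", tmp_path / "cond.tsv")

    def test_non_numeric_cell_names_location(self, tmp_path):
        (tmp_path / "x.tsv").write_text("gene\ts1\ts2\ng1\t1\tow\ng2\t3\t4\n")
        (tmp_path / "cond.tsv").write_text("sample\tcondition\ns1\tA\ns2\tA\n")
        with pytest.raises(CresigError, match="g1.*s2"):
            cio.read_expression(tmp_path / "x.tsv", tmp_path / "cond.tsv")

    def test_unknown_sample_in_condition_map(self, tmp_path):
        (tmp_path / "x.tsv").write_text("gene\ts1\ng1\t1\n")
        (tmp_path / "cond.tsv").write_text("sample\tcondition\ns1\tA\nsX\tB\n")
        with pytest.raises(CresigError, match="sX"):
            cio.read_expression(tmp_path / "x.tsv", tmp_path / "cond.tsv")

    def test_round_trip(self, tmp_path, rng):
        genes = [f"g{i}" for i in range(40)]
        samples = [f"s{i}" for i in range(6)]
        values = pd.DataFrame(rng.normal(8, 2, (40, 6)), index=genes, columns=samples)
        cond = pd.Series({s: ("CT" if i < 3 else "T") for i, s in enumerate(samples)})
        expr = ExpressionMatrix(values, cond)
        cio.write_expression(expr, tmp_path / "x.tsv", tmp_path / "c.tsv")
        back = cio.read_expression(tmp_path / "x.tsv", tmp_path / "c.tsv")
        np.testing.assert_allclose(back.values.to_numpy(), values.to_numpy(), atol=1e-12)
        assert dict(back.conditions) == dict(cond)


class TestGmt:
    def test_dedup_within_line(self, tmp_path):
        (tmp_path / "s.gmt").write_text("S1\tdesc\ta\tb\tb\n")
        coll = cio.read_gmt(tmp_path / "s.gmt")
        assert coll["S1"] == {"a", "b"}

    def test_empty_file(self, tmp_path):
        (tmp_path / "s.gmt").write_text("")
        assert len(cio.read_gmt(tmp_path / "s.gmt")) == 0

    def test_short_line_reports_number(self, tmp_path):
        (tmp_path / "s.gmt").write_text("S1\tdesc\ta\nS2\tonlydesc\n")
        with pytest.raises(CresigError, match=":2"):
            cio.read_gmt(tmp_path / "s.gmt")

    def test_random_round_trip(self, tmp_path, rng):
        sets = {}
        for i in range(100):
            size = int(rng.integers(1, 20))
            sets[f"SET{i:03d}"] = {f"g{int(x)}" for x in rng.integers(0, 500, size)}
        coll = GeneSetCollection(sets)
        cio.write_gmt(coll, tmp_path / "r.gmt")
        back = cio.read_gmt(tmp_path / "r.gmt")
        assert back.sets == coll.sets


JASPAR_CRE = """>CRE
A [ 2 2 94 2 2 2 2 94 ]
C [ 2 2 2 94 2 2 94 2 ]
G [ 2 94 2 2 94 2 2 2 ]
T [ 94 2 2 2 2 94 2 2 ]
"""

TRANSFAC_CRE = """ID CRE
BF test
P0 A C G T
01 2 2 2 94
02 2 2 94 2
03 94 2 2 2
04 2 94 2 2
05 2 2 94 2
06 2 2 2 94
07 2 94 2 2
08 94 2 2 2
XX
//
"""


class TestPwmIO:
    def test_jaspar_width(self, tmp_path):
        (tmp_path / "m.pfm").write_text(JASPAR_CRE)
        pwm = cio.read_pwm(tmp_path / "m.pfm", "jaspar")
        assert pwm.width == 8

    def test_cross_format_equality(self, tmp_path):
        (tmp_path / "m.pfm").write_text(JASPAR_CRE)
        (tmp_path / "m.transfac").write_text(TRANSFAC_CRE)
        a = cio.read_pwm(tmp_path / "m.pfm", "jaspar")
        b = cio.read_pwm(tmp_path / "m.transfac", "transfac")
        np.testing.assert_allclose(a.counts, b.counts)

    def test_zero_width_rejected(self, tmp_path):
        (tmp_path / "m.pfm").write_text(">empty\nA []\nC []\nG []\nT []\n")
        with pytest.raises(CresigError):
            cio.read_pwm(tmp_path / "m.pfm", "jaspar")

    def test_round_trip(self, tmp_path):
        (tmp_path / "m.pfm").write_text(JASPAR_CRE)
        pwm = cio.read_pwm(tmp_path / "m.pfm", "jaspar")
        cio.write_pwm_jaspar(pwm, tmp_path / "out.pfm")
        back = cio.read_pwm(tmp_path / "out.pfm", "jaspar")
        np.testing.assert_allclose(back.counts, pwm.counts, atol=1e-9)


class TestDomainTypes:
    def test_trap_rank_permutation(self, rng):
        n = 50
        trap = TrapList(pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "abundance": rng.exponential(size=n),
        }))
        assert sorted(trap.table["rank"]) == list(range(1, n + 1))
        assert trap.table["abundance"].is_monotonic_decreasing

    def test_deg_direction_invariant(self):
        t = make_deg_table(["a", "b"], [1.0, -1.0])
        validate_deg_table(t)
        t.loc[0, "direction"] = "DOWN"
        with pytest.raises(CresigError):
            validate_deg_table(t)

    def test_runconfig_bounds(self):
        with pytest.raises(CresigError):
            RunConfig(alpha=0.0)
        with pytest.raises(CresigError):
            RunConfig(bin_size=1)
        with pytest.raises(CresigError):
            RunConfig(gsea_n_perm=10)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(CresigError):
            GeneSetCollection({"S": set()})


class TestCli:
    def test_unknown_subcommand(self):
        result = CliRunner().invoke(cli_main, ["frobnicate"])
        assert result.exit_code != 0

    def test_missing_required_flag(self):
        result = CliRunner().invoke(cli_main, ["de"])
        assert result.exit_code != 0
        assert "Usage" in result.output or "Error" in result.output

    def test_de_subcommand(self, tmp_path, small_study):
        from cresig.io import write_expression

        write_expression(small_study.expression["FSK"], tmp_path / "x.tsv", tmp_path / "c.tsv")
        result = CliRunner().invoke(cli_main, [
            "de", "--expr", str(tmp_path / "x.tsv"), "--conditions", str(tmp_path / "c.tsv"),
            "--contrast", "FSK:CT", "--out-dir", str(tmp_path / "de"),
        ])
        assert result.exit_code == 0, result.output
        degs = cio.read_deg_table(tmp_path / "de" / "degs.tsv")
        assert len(degs) > 0

    def test_full_chain_smoke(self, tmp_path):
        """simulate -> de -> filter -> profile -> scanmotif -> gsea -> go ->
        core -> compare, end to end through the CLI on a tiny study."""
        runner = CliRunner()
        sim = tmp_path / "study"

        def run(args):
            res = runner.invoke(cli_main, args, catch_exceptions=False)
            assert res.exit_code == 0, res.output
            return res

        run(["simulate", "--seed", "7", "--out-dir", str(sim),
             "--n-genes", "400", "--n-core", "20"])
        for stim, ctrl in (("FSK", "CT"), ("NE", "CT"), ("VP16", "Null")):
            run(["de", "--expr", str(sim / f"expr_{stim}.tsv"),
                 "--conditions", str(sim / f"conditions_{stim}.tsv"),
                 "--contrast", f"{stim}:{ctrl}", "--out-dir", str(tmp_path / f"de_{stim}")])
        run(["filter", "--deg", str(tmp_path / "de_VP16" / "degs.tsv"),
             "--trap", str(sim / "trap.tsv"), "--out-dir", str(tmp_path / "filt")])
        run(["profile", "--deg", str(tmp_path / "de_VP16" / "stats_all.tsv"),
             "--trap", str(sim / "trap.tsv"), "--bin-size", "100",
             "--out-dir", str(tmp_path / "prof")])
        run(["scanmotif", "--fasta", str(sim / "promoters.fasta"),
             "--pwm", str(sim / "cre_motif.pfm"),
             "--deg", str(tmp_path / "de_VP16" / "stats_all.tsv"),
             "--trap", str(sim / "trap.tsv"), "--bin-size", "100",
             "--out-dir", str(tmp_path / "motif")])
        run(["gsea", "--rnk", str(sim / "invivo.rnk"), "--gmt", str(sim / "go_sets.gmt"),
             "--n-perm", "100", "--seed", "7", "--out-dir", str(tmp_path / "gsea")])
        run(["go", "--deg", str(tmp_path / "de_VP16" / "degs.tsv"),
             "--gmt", str(sim / "go_sets.gmt"), "--universe", str(sim / "universe.txt"),
             "--out-dir", str(tmp_path / "go")])
        run(["core",
             "--deg", "FSK", str(tmp_path / "de_FSK" / "degs.tsv"),
             "--deg", "NE", str(tmp_path / "de_NE" / "degs.tsv"),
             "--deg", "VP16", str(tmp_path / "de_VP16" / "degs.tsv"),
             "--trap", str(sim / "trap.tsv"), "--registry", str(sim / "registry.txt"),
             "--out-dir", str(tmp_path / "core")])
        run(["compare", "--sig-a", str(tmp_path / "core" / "core_signature.tsv"),
             "--sig-b", str(tmp_path / "core" / "core_signature.tsv"),
             "--out-dir", str(tmp_path / "cmp")])
        summary = json.loads((tmp_path / "cmp" / "compare_summary.json").read_text())
        assert summary["n_shared"] == len(summary["shared"])
        core_summary = json.loads((tmp_path / "core" / "core_summary.json").read_text())
        assert core_summary["counts"]["shared"] >= core_summary["counts"]["up_in_all"]

    def test_rerun_is_byte_identical(self, tmp_path):
        runner = CliRunner()
        for d in ("a", "b"):
            res = runner.invoke(cli_main, [
                "simulate", "--seed", "3", "--out-dir", str(tmp_path / d),
                "--n-genes", "300", "--n-core", "15",
            ], catch_exceptions=False)
            assert res.exit_code == 0
        for name in ("expr_FSK.tsv", "trap.tsv", "promoters.fasta", "truth.tsv", "invivo.rnk"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
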