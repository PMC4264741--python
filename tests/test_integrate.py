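"""Evidence merging, VCF emission and the end-to-end pipeline."""

import numpy as np
import pytest

from svcall.doc import CnvSegment
from svcall.integrate import (
    PipelineConfig,
    SVCall,
    merge_calls,
    read_vcf,
    reciprocal_overlap,
    run_pipeline,
    write_vcf,
)
from svcall.sv_typing import SVType

CONTIGS = [("chr1", 2_000_000), ("chr2", 2_000_000)]


def _cluster_call(i, svtype=SVType.DEL, chrom="chr1", pos1=10_000, pos2=20_000,
                  support=10, **kw):
    return SVCall(
        id=f"cl{i}", svtype=svtype, chrom1=chrom, pos1=pos1,
        ci1=(pos1 - 500, pos1 + 500), chrom2=kw.pop("chrom2", chrom),
        pos2=pos2, ci2=(pos2 - 500, pos2 + 500),
        length=abs(pos2 - pos1) if chrom == kw.get("chrom2", chrom) else None,
        evidence={"cluster"}, support=support, **kw,
    )


def _seg(chrom="chr1", start=11_000, end=19_000, lr=-1.0, n=40):
    return CnvSegment(chrom=chrom, start=start, end=end, mean_log2_ratio=lr,
                      direction="loss" if lr < 0 else "gain", n_windows=n,
                      window_span=200)


class TestReciprocalOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        ((0, 100), (0, 100), 1.0),
        ((10_000, 20_000), (11_000, 19_000), 0.8),
        ((0, 100), (200, 300), 0.0),
        ((0, 100), (50, 250), 0.25),
    ])
    def test_values(self, a, b, expected):
        assert reciprocal_overlap(a, b) == pytest.approx(expected)


class TestMergeCalls:
    def test_del_cluster_merges_with_loss_segment(self):
        calls = merge_calls([_cluster_call(0)], [_seg()], 0.5)
        assert len(calls) == 1
        assert calls[0].evidence == {"cluster", "doc"}
        assert calls[0].log2_ratio == pytest.approx(-1.0)
        assert calls[0].support == 10

    def test_sign_conflict_yields_two_calls_and_tag(self):
        calls = merge_calls([_cluster_call(0)], [_seg(lr=1.0)], 0.5)
        assert len(calls) == 2
        dele = next(c for c in calls if c.svtype is SVType.DEL and c.support > 0)
        assert "discordant_evidence" in dele.filters
        assert dele.evidence == {"cluster"}

    def test_copy_neutral_types_never_merge(self):
        inv = _cluster_call(0, svtype=SVType.INV)
        calls = merge_calls([inv], [_seg()], 0.5)
        assert len(calls) == 2
        assert next(c for c in calls if c.svtype is SVType.INV).evidence == {"cluster"}

    def test_unmatched_segment_becomes_imprecise_doc_call(self):
        calls = merge_calls([], [_seg(start=500_000, end=520_000, lr=0.9)], 0.5)
        assert len(calls) == 1
        assert calls[0].evidence == {"doc"}
        assert calls[0].svtype is SVType.DUP
        assert calls[0].imprecise and calls[0].support == 0

    def test_every_input_represented_once(self):
        clusters = [_cluster_call(i, pos1=100_000 * (i + 1),
                                  pos2=100_000 * (i + 1) + 10_000)
                    for i in range(4)]
        segs = [_seg(start=100_000 * (i + 1) + 500,
                     end=100_000 * (i + 1) + 9_500) for i in range(2)]
        out = merge_calls(clusters, segs, 0.5)
        assert len(out) == len(clusters)  # both segments merged into calls
        assert sum(c.evidence == {"cluster", "doc"} for c in out) == 2
        assert len(out) <= len(clusters) + len(segs)

    def test_output_sorted(self):
        clusters = [_cluster_call(0, chrom="chr2", chrom2="chr2"),
                    _cluster_call(1, pos1=900_000, pos2=910_000),
                    _cluster_call(2, pos1=5_000, pos2=15_000)]
        out = merge_calls(clusters, [], 0.5)
        keys = [(c.chrom1, c.pos1) for c in out]
        assert keys == sorted(keys)


class TestVcf:
    def _calls(self):
        return [
            _cluster_call(0, pos1=999, pos2=4999, support=12),
            _cluster_call(1, svtype=SVType.DUP, pos1=50_000, pos2=60_000),
            _cluster_call(2, svtype=SVType.TRA, chrom="chr1", chrom2="chr2",
                          pos1=100_000, pos2=200_000, strands=("+", "-")),
            _cluster_call(3, svtype=SVType.INV, pos1=300_000, pos2=312_000),
        ]

    def test_del_coordinate_convention(self, tmp_path):
        path = tmp_path / "c.vcf"
        write_vcf(self._calls(), CONTIGS, str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        del_line = next(l for l in body if "<DEL>" in l)
        fields = del_line.split("\t")
        assert fields[1] == "999"
        assert "END=4999" in fields[7]
        assert "SVLEN=-4000" in fields[7]

    def test_tra_paired_bnd_records(self, tmp_path):
        path = tmp_path / "c.vcf"
        write_vcf(self._calls(), CONTIGS, str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        bnds = [l.split("\t") for l in body if "SVTYPE=BND" in l]
        assert len(bnds) == 2
        ids = {f[2] for f in bnds}
        mates = {f[7].split("MATEID=")[1].split(";")[0] for f in bnds}
        assert ids == mates  # cross-referencing mate pair
        assert any("[" in f[4] or "]" in f[4] for f in bnds)

    def test_roundtrip_idempotent(self, tmp_path):
        a = tmp_path / "a.vcf"
        b = tmp_path / "b.vcf"
        write_vcf(self._calls(), CONTIGS, str(a))
        back = read_vcf(str(a))
        assert len(back) == len(self._calls())
        write_vcf(back, CONTIGS, str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_unknown_chromosome_rejected(self, tmp_path):
        call = _cluster_call(0, chrom="chrUn", chrom2="chrUn")
        with pytest.raises(ValueError, match="chrUn"):
            write_vcf([call], CONTIGS, str(tmp_path / "x.vcf"))


@pytest.fixture(scope="module")
def pipeline_sam(tmp_path_factory, small_sim):
    """Small-scenario sample + SV-free reference sample written as SAM."""
    from svcall.simulate import apply_svs, sample_pairs, write_sam

    d = tmp_path_factory.mktemp("pipe")
    sam = d / "sample.sam"
    ref_sam = d / "reference.sam"
    write_sam(small_sim.records, small_sim.contigs, str(sam), read_len=50)
    _, null_manifest = apply_svs(small_sim.reference, [], seed=42)
    ref_records = sample_pairs(null_manifest, coverage=10.0, seed=43)
    write_sam(ref_records, small_sim.contigs, str(ref_sam), read_len=50)
    return str(sam), str(ref_sam)


class TestPipeline:
    def test_sample_only_run_skips_doc(self, pipeline_sam, tmp_path):
        sam, _ = pipeline_sam
        res = run_pipeline(PipelineConfig(sample=sam, out_dir=str(tmp_path / "o")))
        assert res.windows == [] and res.segments == []
        assert any("DOC stage skipped" in l for l in res.log)
        assert all(c.evidence == {"cluster"} for c in res.calls)
        assert (tmp_path / "o" / "calls.vcf").exists()
        assert (tmp_path / "o" / "clusters.bedpe").exists()
        assert (tmp_path / "o" / "run.log").exists()

    def test_full_run_recovers_truth(self, pipeline_sam, small_sim, tmp_path):
        sam, ref_sam = pipeline_sam
        res = run_pipeline(PipelineConfig(sample=sam, ref_sample=ref_sam,
                                          out_dir=str(tmp_path / "o")))
        called_types = {c.svtype.value for c in res.calls}
        truth_types = {sv.svtype for sv in small_sim.manifest.svs}
        assert truth_types <= called_types
        # every call sits at an implanted junction
        sigma = res.model.sigma_is
        for c in res.calls:
            d = min(
                abs(c.pos1 - bp[1])
                for sv in small_sim.manifest.svs
                for bp in sv.breakpoints
                if bp[0] == c.chrom1
            )
            assert d <= max(res.model.median_is, 2 * sigma) + 2 * sigma
        # deletions/duplications carry coverage corroboration
        for t in ("DEL", "DUP"):
            assert any(c.svtype.value == t and c.evidence == {"cluster", "doc"}
                       for c in res.calls), t
        assert (tmp_path / "o" / "doc_segments.bed").exists()
        assert (tmp_path / "o" / "doc_ratio.bedgraph").exists()

    def test_rerun_determinism(self, pipeline_sam, tmp_path):
        sam, ref_sam = pipeline_sam
        outs = []
        for tag in ("a", "b"):
            out = tmp_path / tag
            run_pipeline(PipelineConfig(sample=sam, ref_sample=ref_sam,
                                        out_dir=str(out)))
            outs.append((out / "calls.vcf").read_bytes())
        assert outs[0] == outs[1]

    def test_cli_run(self, pipeline_sam, tmp_path):
        from click.testing import CliRunner

        from svcall.cli import main

        sam, ref_sam = pipeline_sam
        out = tmp_path / "cli_out"
        runner = CliRunner()
        result = runner.invoke(
            main, ["run", "--bam", sam, "--ref-bam", ref_sam, "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert (out / "calls.vcf").exists()

    def test_cli_simulate(self, tmp_path):
        from click.testing import CliRunner

        from svcall.cli import main

        cfg = tmp_path / "scenario.yaml"
        cfg.write_text(
            "chrom_lengths: [120000]\ncoverage: 4\n"
            "svs:\n  - {svtype: DEL, chrom: chr1, pos: 50000, length: 8000}\n"
        )
        out = tmp_path / "sim"
        runner = CliRunner()
        result = runner.invoke(
            main, ["simulate", "--config", str(cfg), "--seed", "2",
                   "--out", str(out), "--no-reference-sample"]
        )
        assert result.exit_code == 0, result.output
        assert (out / "sample.sam").exists()
        assert (out / "truth.bedpe").exists()
        assert (out / "reference.fa").exists()
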