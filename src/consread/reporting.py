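"""Run statistics and the JSON / standalone HTML reports.

A summary of the data is collected both before (``pre``) and after (``post``)
processing: read and base counters, mapping rate, mismatch rate against the
reference (by direct base comparison, so it stays correct on consensus output
whose MD tags are not regenerated), genome-scale coverage in fixed-width
bins, per-capture-region coverage when a BED is given, plus the duplication
histogram and the cluster passing-filter rate.

The HTML report is a single self-contained page: the charts are inline SVG
(hover a bar for its value), so the file needs no network access to view.
Every number shown in the HTML is rendered through the same JSON serializer
as the JSON report, so the two always agree character-for-character.
"""

from __future__ import annotations

import bisect
import json
from html import escape
from typing import Optional

from .core_model import AlignedRead, RunStats

DEFAULT_COVERAGE_BIN = 10_000


def accumulate(
    stats: RunStats,
    record: AlignedRead,
    reference,
    phase: str,
    coverage_bin: int = DEFAULT_COVERAGE_BIN,
) -> None:
    """Fold one alignment record into the pre- or post-phase counters."""
    counters = stats.phase(phase)
    counters.total_reads += 1
    counters.total_bases += len(record.seq)
    if record.is_unmapped or record.chrom is None:
        return
    counters.mapped_reads += 1

    chrom = record.chrom
    bins = stats.coverage_bins[phase].setdefault(chrom, {})
    region_starts, region_index = _regions_for(stats, chrom)
    bed_acc = stats.bed_bases[phase]

    for qpos, rpos in record.aligned_pairs():
        counters.aligned_bases += 1
        base = record.seq[qpos]
        if base != "N" and reference is not None:
            if base != reference.get_base(chrom, rpos):
                counters.mismatched_bases += 1
        b = rpos // coverage_bin
        bins[b] = bins.get(b, 0) + 1
        if region_starts:
            i = bisect.bisect_right(region_starts, rpos) - 1
            if i >= 0:
                ridx = region_index[i]
                if rpos < stats.bed_regions[ridx][2]:
                    bed_acc[ridx] += 1


def _regions_for(stats: RunStats, chrom: str) -> tuple[list[int], list[int]]:
    # per-chromosome sorted starts with back-pointers into bed_regions
    cache = getattr(stats, "_region_cache", None)
    if cache is None:
        cache = {}
        for i, (c, s, _e) in enumerate(stats.bed_regions):
            cache.setdefault(c, ([], []))
            cache[c][0].append(s)
            cache[c][1].append(i)
        object.__setattr__(stats, "_region_cache", cache)
    return cache.get(chrom, ([], []))


def init_bed(stats: RunStats, regions: list[tuple[str, int, int]]) -> None:
    stats.bed_regions = list(regions)
    stats.bed_bases = {"pre": [0] * len(regions), "post": [0] * len(regions)}
    if hasattr(stats, "_region_cache"):
        object.__delattr__(stats, "_region_cache")


def record_cluster(stats: RunStats, cluster_size: int, passed: bool) -> None:
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    stats.duplication_histogram[cluster_size] = (
        stats.duplication_histogram.get(cluster_size, 0) + 1
    )
    stats.clusters_total += 1
    if passed:
        stats.clusters_passing += 1


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def finalize(
    stats: RunStats,
    options: Optional[dict] = None,
    genome_lengths: Optional[dict[str, int]] = None,
    coverage_bin: int = DEFAULT_COVERAGE_BIN,
) -> dict:
    """Assemble the report model (a plain dict, ready for JSON)."""
    from . import __version__

    def phase_block(name: str) -> dict:
        c = stats.phase(name)
        mean_depth = None
        if genome_lengths:
            total_len = sum(genome_lengths.values())
            mean_depth = _ratio(c.aligned_bases, total_len)
        return {
            "total_reads": c.total_reads,
            "mapped_reads": c.mapped_reads,
            "total_bases": c.total_bases,
            "aligned_bases": c.aligned_bases,
            "mismatched_bases": c.mismatched_bases,
            "mapping_rate": c.mapping_rate,
            "mismatch_rate": c.mismatch_rate,
            "mean_depth": mean_depth,
        }

    duplication_rate = None
    if stats.pairs_total > 0:
        duplication_rate = 1.0 - stats.clusters_total / stats.pairs_total

    histogram = {
        str(size): stats.duplication_histogram[size]
        for size in sorted(stats.duplication_histogram)
    }

    coverage = {"bin_width": coverage_bin, "chromosomes": {}}
    chroms = sorted(
        set(stats.coverage_bins["pre"]) | set(stats.coverage_bins["post"])
    )
    for chrom in chroms:
        pre_bins = stats.coverage_bins["pre"].get(chrom, {})
        post_bins = stats.coverage_bins["post"].get(chrom, {})
        n_bins = max([*pre_bins, *post_bins], default=-1) + 1
        coverage["chromosomes"][chrom] = {
            "pre": [pre_bins.get(i, 0) for i in range(n_bins)],
            "post": [post_bins.get(i, 0) for i in range(n_bins)],
        }

    bed_block = []
    for i, (chrom, start, end) in enumerate(stats.bed_regions):
        length = end - start
        bed_block.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "mean_depth_pre": stats.bed_bases["pre"][i] / length,
                "mean_depth_post": stats.bed_bases["post"][i] / length,
            }
        )

    return {
        "summary": {
            "pairs_total": stats.pairs_total,
            "clusters_total": stats.clusters_total,
            "clusters_passing": stats.clusters_passing,
            "consensus_written": stats.consensus_written,
            "passthrough_reads": stats.passthrough_reads,
            "orphan_pairs": stats.orphan_pairs,
            "excluded_members": stats.excluded_members,
            "ref_corrected_bases": stats.ref_corrected_bases,
            "duplication_rate": duplication_rate,
            "passing_filter_rate": _ratio(stats.clusters_passing, stats.clusters_total),
        },
        "pre_filtering": phase_block("pre"),
        "post_filtering": phase_block("post"),
        "duplication_histogram": histogram,
        "coverage": coverage,
        "bed_regions": bed_block if stats.bed_regions else None,
        "options": options or {},
        "version": __version__,
    }


def write_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# HTML rendering
# ---------------------------------------------------------------------------

def _num(value) -> str:
    """Render a number exactly as the JSON report does."""
    return json.dumps(value)


def _svg_bars(
    labels: list[str], values: list[float], title: str, color: str = "#3b6ea5"
) -> str:
    if not values:
        return "<p>(no data)</p>"
    width, height, pad = 640, 180, 28
    vmax = max(values) or 1
    n = len(values)
    bw = max((width - pad) / n, 1.0)
    bars = []
    for i, (label, v) in enumerate(zip(labels, values)):
        h = (v / vmax) * (height - pad)
        x = pad + i * bw
        y = height - pad - h
        bars.append(
            f'<rect x="{x:.1f}" y="{y:.1f}" width="{max(bw - 1, 0.5):.1f}" '
            f'height="{h:.1f}" fill="{color}">'
            f"<title>{escape(label)}: {escape(_num(v))}</title></rect>"
        )
    return (
        f'<figure><figcaption>{escape(title)}</figcaption>'
        f'<svg viewBox="0 0 {width} {height}" width="{width}" height="{height}" '
        f'role="img">{"".join(bars)}'
        f'<line x1="{pad}" y1="{height - pad}" x2="{width}" y2="{height - pad}" '
        f'stroke="#333"/></svg></figure>'
    )


def _kv_table(rows: list[tuple[str, object]]) -> str:
    body = "".join(
        f"<tr><td>{escape(k)}</td><td class='v'>{escape(_num(v))}</td></tr>"
        for k, v in rows
    )
    return f"<table>{body}</table>"


def write_html(report: dict, path: str) -> None:
    """Render the report model as one self-contained HTML page."""
    parts: list[str] = []
    parts.append(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>consread report</title><style>"
        "body{font-family:sans-serif;margin:2em;max-width:60em}"
        "table{border-collapse:collapse;margin:0.6em 0}"
        "td{border:1px solid #ccc;padding:2px 8px}td.v{text-align:right}"
        "figure{margin:1em 0}figcaption{font-weight:bold;margin-bottom:4px}"
        "h2{border-bottom:1px solid #999}"
        "</style></head><body>"
    )
    parts.append(f"<h1>consread report (v{escape(str(report['version']))})</h1>")

    parts.append("<h2>Summary</h2>")
    parts.append(_kv_table(list(report["summary"].items())))

    for phase_key, title in (
        ("pre_filtering", "Before processing"),
        ("post_filtering", "After processing"),
    ):
        parts.append(f"<h2>{title}</h2>")
        parts.append(_kv_table(list(report[phase_key].items())))

    hist = report["duplication_histogram"]
    parts.append("<h2>Duplication histogram</h2>")
    parts.append(_kv_table(list(hist.items())))
    parts.append(
        _svg_bars(
            [f"duplication level {k}" for k in hist],
            [float(v) for v in hist.values()],
            "Clusters per duplication level",
        )
    )

    parts.append("<h2>Mismatch rate</h2>")
    pre_mr = report["pre_filtering"]["mismatch_rate"]
    post_mr = report["post_filtering"]["mismatch_rate"]
    parts.append(
        _kv_table([("pre", pre_mr), ("post", post_mr)])
    )
    if pre_mr is not None and post_mr is not None:
        parts.append(
            _svg_bars(["pre", "post"], [pre_mr, post_mr], "Mismatch rate", "#a54242")
        )

    parts.append("<h2>Genome-scale coverage</h2>")
    cov = report["coverage"]
    parts.append(f"<p>bin width: {escape(_num(cov['bin_width']))} bp</p>")
    for chrom, series in cov["chromosomes"].items():
        labels = [f"{chrom} bin {i}" for i in range(len(series["post"]))]
        parts.append(
            _svg_bars(labels, [float(v) for v in series["post"]],
                      f"{chrom} aligned bases per bin (post)")
        )

    if report["bed_regions"]:
        parts.append("<h2>Capture-region coverage</h2>")
        rows = "".join(
            "<tr>"
            f"<td>{escape(r['chrom'])}</td>"
            f"<td class='v'>{escape(_num(r['start']))}</td>"
            f"<td class='v'>{escape(_num(r['end']))}</td>"
            f"<td class='v'>{escape(_num(r['mean_depth_pre']))}</td>"
            f"<td class='v'>{escape(_num(r['mean_depth_post']))}</td>"
            "</tr>"
            for r in report["bed_regions"]
        )
        parts.append(
            "<table><tr><th>chrom</th><th>start</th><th>end</th>"
            "<th>mean depth pre</th><th>mean depth post</th></tr>"
            f"{rows}</table>"
        )
        parts.append(
            _svg_bars(
                [f"{r['chrom']}:{r['start']}-{r['end']}" for r in report["bed_regions"]],
                [r["mean_depth_post"] for r in report["bed_regions"]],
                "Mean depth per capture region (post)",
                "#2e8b57",
            )
        )

    parts.append("</body></html>")
    with open(path, "w") as fh:
        fh.write("".join(parts))
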