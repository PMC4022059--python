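"""Bundled reference tables.

The reactor-comparison study tabulates, for dilute-acid-pretreated corn
stover from three reactor configurations plus the untreated control,
the enzymatic glucan release together with composition and the four
image-derived structural parameters.  The published per-sample values
are bundled here so the correlation stage can be demonstrated and
checked without the original micrographs.

Reactor codes: ZC = ZipperClave (batch, gradual depressurization),
SG = steam gun (batch, explosive discharge), HS = horizontal screw
(continuous, explosive discharge with mechanical shear).
"""

from __future__ import annotations

from .correlate import SampleSummary

__all__ = ["reactor_study_summaries"]


def reactor_study_summaries() -> list[SampleSummary]:
    """Published per-sample summary rows of the reactor-comparison study.

    Units: glucan release, xylan, lignin and delamination/porosity in %;
    degree of polymerization dimensionless; particle size as mean
    projected area in mm²; cell wall thickness in µm; surface roughness
    in grayscale-SD units.
    """
    return [
        SampleSummary(
            sample_id="Untreated",
            glucan_release=24.0,
            xylan=22.0,
            lignin=12.3,
            degree_of_polymerization=2000.0,
            particle_size=0.15,
            aspect_ratio=1.78,
            cell_wall_thickness=1.29,
            surface_roughness=7.60,
            delamination_porosity=3.41,
            pretreated=False,
        ),
        SampleSummary(
            sample_id="ZC",
            glucan_release=68.7,
            xylan=8.8,
            lignin=24.2,
            degree_of_polymerization=1750.0,
            particle_size=0.08,
            aspect_ratio=1.90,
            cell_wall_thickness=3.49,
            surface_roughness=10.37,
            delamination_porosity=5.62,
        ),
        SampleSummary(
            sample_id="SG",
            glucan_release=88.0,
            xylan=4.8,
            lignin=25.0,
            degree_of_polymerization=1650.0,
            particle_size=0.08,
            aspect_ratio=1.67,
            cell_wall_thickness=2.60,
            surface_roughness=17.53,
            delamination_porosity=20.01,
        ),
        SampleSummary(
            sample_id="HS",
            glucan_release=95.2,
            xylan=3.2,
            lignin=24.8,
            degree_of_polymerization=1850.0,
            particle_size=0.07,
            aspect_ratio=1.49,
            cell_wall_thickness=2.30,
            surface_roughness=17.61,
            delamination_porosity=26.57,
        ),
    ]
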