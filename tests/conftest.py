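import pytest

from scembi import (
    GeneratorConfig,
    cell_quantify,
    counts_to_mass,
    fit_calibration,
    generate_droplet_array,
    generate_tumor_image,
)


@pytest.fixture(scope="session")
def calibration_model():
    """Zero-intercept Pt calibration fitted on a default droplet array."""
    droplets = generate_droplet_array(GeneratorConfig(seed=0))
    return fit_calibration(droplets, "Pt", force_zero_intercept=True)


@pytest.fixture(scope="session")
def tumor():
    """Default resistant-layout tumor image with ground truth (600x600 um)."""
    return generate_tumor_image(GeneratorConfig(seed=3, image_size=(600, 600)))


@pytest.fixture(scope="session")
def tumor_cells(tumor, calibration_model):
    """Cell table quantified on the ground-truth mask of the tumor fixture."""
    image, truth = tumor
    mass, _ = counts_to_mass(image.get("Pt"), calibration_model)
    cells = cell_quantify(mass, truth.cell_mask_true, image)
    cells = cells.copy()
    cells["phenotype_true"] = truth.cell_phenotype_true
    return cells


@pytest.fixture(scope="session")
def control_cells(calibration_model):
    """Control-tissue cell table (compound-Poisson background only)."""
    cfg = GeneratorConfig(seed=11, region_layout="control", image_size=(800, 800))
    image, truth = generate_tumor_image(cfg)
    mass, _ = counts_to_mass(image.get("Pt"), calibration_model)
    return cell_quantify(mass, truth.cell_mask_true, image)
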