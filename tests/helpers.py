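import numpy as np
import pandas as pd
from boarpop.io import GenotypeMatrix, MarkerMap, SampleTable


def build_markers(n_loci, chromosome="1", spacing_bp=100_000, start_bp=100_000,
                  alleles=("A", "G")):
    """Evenly spaced markers on one chromosome."""
    return MarkerMap(
        pd.DataFrame(
            {
                "locus_id": [f"snp{j}" for j in range(n_loci)],
                "chromosome": chromosome,
                "position_bp": start_bp + spacing_bp * np.arange(n_loci),
                "allele_a": alleles[0],
                "allele_b": alleles[1],
            }
        )
    )


def build_genotypes(dosage, markers=None, groups="wild", location_ids=None,
                    longitudes=None, latitudes=None, cluster_ids=None):
    """GenotypeMatrix from a dosage array with generated ids/metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    markers = markers or build_markers(m)
    tab = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "group": [groups] * n if isinstance(groups, str) else list(groups),
        }
    )
    if location_ids is not None:
        tab["location_id"] = list(location_ids)
    if longitudes is not None:
        tab["longitude"] = list(longitudes)
    if latitudes is not None:
        tab["latitude"] = list(latitudes)
    if cluster_ids is not None:
        tab["cluster_id"] = list(cluster_ids)
    return GenotypeMatrix(markers, SampleTable(tab), dosage)


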