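# Default repository -> category key mappings.
#
# Each key listed under title/keywords/description is matched as a
# case-insensitive suffix of the flattened (dot-joined) JSON key paths
# found in a record's METADATA payload, in the order given. Matched values
# are concatenated with single spaces to build the category text.
#
# The geo mapping uses only keys present in the record itself; no online
# augmentation is performed.
arrayexpress:
  title: [title]
  keywords: []
  description: [description]
bioproject:
  title: [title]
  keywords: [dataItemkeywords]
  description: [organismtargetspecies, dataItemdescription]
cia:
  title: [title]
  keywords: []
  description: [anatomicalPartname, diseasename, organismname, organismscientificname]
clinicaltrials:
  title: [title]
  keywords: [keyword]
  description: [criteria, StudyGroupdescription, Diseasename, Treatmentdescription, Treatmentagent, Datasetdescription]
ctn:
  title: [title]
  keywords: [datasetkeywords]
  description: [datasetdescription, organismscientificName, organismname]
cvrg:
  title: [title]
  keywords: []
  description: [datasetdescription]
dataverse:
  title: [title]
  keywords: []
  description: [publicationdescription, datasetdescription]
dryad:
  title: [title]
  keywords: [datasetkeywords]
  description: [datasetdescription]
gemma:
  title: [title]
  keywords: []
  description: [dataItemdescription, organismcommonName]
geo:
  title: [title]
  keywords: []
  description: [dataItemsource_name, dataItemorganism, dataItemdescription]
mpd:
  title: [title]
  keywords: []
  description: [datasetdescription, organismscientificName, organismname]
neuromorpho:
  title: [title]
  keywords: []
  description: [anatomicalPartname, cellname, organismscientificName, organismname]
nursadatasets:
  title: [title]
  keywords: [datasetkeywords]
  description: [datasetdescription, organismname]
openfmri:
  title: [title]
  keywords: []
  description: [datasetdescription]
pdb:
  title: [title]
  keywords: [dataItemkeywords]
  description: [dataItemdescription, organismsourcescientificName, organismhostscientificName, genename]
peptideatlas:
  title: [title]
  keywords: []
  description: [datasetdescription, treatmentdescription]
phenodisco:
  title: [title]
  keywords: []
  description: [inexclude, desc, disease, history]
physiobank:
  title: [title]
  keywords: []
  description: [datasetdescription]
proteomexchange:
  title: [title]
  keywords: [keywords]
  description: [organismname]
yped:
  title: [title]
  keywords: []
  description: [datasetdescription, organismname]
unknown:
  title: [title]
  keywords: []
  description: [description]
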