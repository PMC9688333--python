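subject_id,class_label,condition
lung_cancer_00,lung_cancer,lung cancer
lung_cancer_01,lung_cancer,lung cancer
lung_cancer_02,lung_cancer,lung cancer
lung_cancer_03,lung_cancer,lung cancer
lung_cancer_04,lung_cancer,lung cancer
lung_cancer_05,lung_cancer,lung cancer
lung_cancer_06,lung_cancer,lung cancer
lung_cancer_07,lung_cancer,lung cancer
lung_cancer_08,lung_cancer,lung cancer
lung_cancer_09,lung_cancer,lung cancer
lung_cancer_10,lung_cancer,lung cancer
lung_cancer_11,lung_cancer,lung cancer
lung_cancer_12,lung_cancer,lung cancer
lung_cancer_13,lung_cancer,lung cancer
lung_cancer_14,lung_cancer,lung cancer
other_cancer_00,other_cancer,breast cancer
other_cancer_01,other_cancer,ovarian cancer
other_cancer_02,other_cancer,peritoneal cancer
other_cancer_03,other_cancer,malignant mesothelioma
other_cancer_04,other_cancer,malignant mesothelioma
other_cancer_05,other_cancer,multiple myeloma
other_cancer_06,other_cancer,lymphoma
control_00,control,exudate
control_01,control,exudate
control_02,control,exudate
control_03,control,exudate
control_04,control,exudate
control_05,control,exudate
control_06,control,exudate
control_07,control,exudate
control_08,control,transudate
control_09,control,transudate
control_10,control,transudate
control_11,control,transudate
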