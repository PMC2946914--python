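category,code_system,code,policy,description
condition,ICD9CM,282*,chronic,hereditary hemolytic anemias
condition,ICD9CM,284*,chronic,aplastic anemia
condition,ICD9CM,200*,chronic,lymphosarcoma / reticulosarcoma
condition,ICD9CM,201*,chronic,Hodgkin disease
condition,ICD9CM,202*,chronic,other lymphoid/histiocytic malignancy
condition,ICD9CM,203*,chronic,multiple myeloma
condition,ICD9CM,204*,chronic,lymphoid leukemia
condition,ICD9CM,205*,chronic,myeloid leukemia
condition,ICD9CM,155.0,chronic,primary liver malignancy
condition,ICD9CM,571.5,chronic,cirrhosis of liver without alcohol
condition,ICD9CM,571.2,chronic,alcoholic cirrhosis of liver
condition,ICD9CM,579*,chronic,intestinal malabsorption
transplant,ICD9CM,V42*,chronic,organ or tissue replaced by transplant
transplant,ICD9PROC,41.0*,chronic,bone marrow or stem cell transplant
transplant,ICD9PROC,55.6*,chronic,kidney transplant
transplant,CPT4,38240,chronic,hematopoietic progenitor cell allogeneic transplantation
transplant,CPT4,50360,chronic,renal allotransplantation
medication_code,CPT4,96400,medication,chemotherapy administration subcutaneous/intramuscular
medication_code,CPT4,96401,medication,chemotherapy administration non-hormonal antineoplastic
medication_code,CPT4,96409,medication,chemotherapy administration intravenous push
medication_code,CPT4,96413,medication,chemotherapy administration intravenous infusion
medication_code,CPT4,96521,medication,refilling and maintenance of portable pump
surgery_blood_loss,CPT4,00560,surgery,anesthesia for heart/pericardium procedures without pump
surgery_blood_loss,CPT4,00670,surgery,anesthesia for extensive spine and spinal cord procedures
surgery_blood_loss,CPT4,00790,surgery,anesthesia for intraperitoneal upper-abdomen procedures
surgery_blood_loss,CPT4,00840,surgery,anesthesia for intraperitoneal lower-abdomen procedures
surgery_blood_loss,CPT4,01214,surgery,anesthesia for total hip arthroplasty
surgery_blood_loss,CPT4,01402,surgery,anesthesia for total knee arthroplasty
surgery_blood_loss,ICD9PROC,81.51,surgery,total hip replacement
surgery_blood_loss,ICD9PROC,81.54,surgery,total knee replacement
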