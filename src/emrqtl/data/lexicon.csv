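name,drug_class
methotrexate,antimetabolite chemotherapy
azathioprine,immunosuppressant
Imuran,immunosuppressant
cyclophosphamide,alkylating chemotherapy
Cytoxan,alkylating chemotherapy
hydroxyurea,antimetabolite chemotherapy
mercaptopurine,antimetabolite chemotherapy
Purinethol,antimetabolite chemotherapy
mycophenolate mofetil,immunosuppressant
CellCept,immunosuppressant
cyclosporine,immunosuppressant
Neoral,immunosuppressant
tacrolimus,immunosuppressant
Prograf,immunosuppressant
capecitabine,antimetabolite chemotherapy
Xeloda,antimetabolite chemotherapy
imatinib,tyrosine kinase inhibitor
Gleevec,tyrosine kinase inhibitor
chlorambucil,alkylating chemotherapy
Leukeran,alkylating chemotherapy
fluorouracil,antimetabolite chemotherapy
busulfan,alkylating chemotherapy
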